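group,own_ms,control_ms
ten,631,538
ten,711,634
ten,535,520
ten,778,762
ten,629,634
ten,463,520
ten,682,658
ten,491,520
ten,722,754
ten,700,658
ten,508,520
ten,589,634
ten,780,658
ten,707,634
ten,833,762
one,639,600
one,800,803
one,725,576
one,748,795
one,709,727
one,595,824
one,724,717
one,537,439
one,540,494
one,537,629
one,669,734
one,840,671
one,585,720
one,440,720
one,606,665
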