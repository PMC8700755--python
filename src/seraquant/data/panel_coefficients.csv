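analyte,coefficient
B1,1019
B2,136.7
B3,61.42
B4,458.7
B5,1507
B6,21.46
B7,5.474
B8,32.66
B9,7.744
B10,2.815
B11,2.768
B12,4.447
B13,3.685
B14,5.474
B15,167.9
B16,51.32
B17,65.93
B18,106.8
B19,37.16
B20,3.81
B21,2.084
B22,227
B23,3.623
B24,531.8
B25,78.53
B26,53.8
B27,317.2
B28,768.2
B29,8554
B30,88.48
B31,329.7
B32,309.4
B33,247.2
B34,220.8
B35,131.4
B36,1157
B37,65.47
B38,489.8
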