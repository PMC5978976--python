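hvl_mm_al,field_side_cm,bsf
1.0,2,1.08
1.0,5,1.15
1.0,10,1.19
1.0,15,1.21
1.0,20,1.22
1.0,30,1.22
2.0,2,1.10
2.0,5,1.20
2.0,10,1.26
2.0,15,1.28
2.0,20,1.29
2.0,30,1.30
4.0,2,1.12
4.0,5,1.26
4.0,10,1.33
4.0,15,1.36
4.0,20,1.38
4.0,30,1.39
6.0,2,1.13
6.0,5,1.29
6.0,10,1.38
6.0,15,1.42
6.0,20,1.44
6.0,30,1.45
8.0,2,1.14
8.0,5,1.31
8.0,10,1.41
8.0,15,1.46
8.0,20,1.49
8.0,30,1.50
10.0,2,1.14
10.0,5,1.32
10.0,10,1.43
10.0,15,1.49
10.0,20,1.52
10.0,30,1.54
12.0,2,1.14
12.0,5,1.33
12.0,10,1.44
12.0,15,1.50
12.0,20,1.54
12.0,30,1.56
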