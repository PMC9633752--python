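patient_id,poor_response,age,rx_dose,n_fractions,total_bed,bed_per_fx,tumor_size,diagnosis
1,Yes,66,45,5,85.5,17.1,4.3,HCC
2,No,62,50,5,100,20,2,LM
3,No,70,50,5,100,20,7.8,HCC
4,Yes,66,45,5,85.5,17.1,1.3,LM
5,Yes,56,50,5,100,20,3.1,LM
6,Yes,74,50,5,100,20,2.1,LM
7,No,92,50,5,100,20,7.2,HCC
8,No,81,40,4,80,20,1.8,LM
9,No,75,50,5,100,20,3.9,HCC
10,No,79,50,5,100,20,4.3,ICC
11,No,70,50,5,100,20,2.7,HCC
12,No,90,50,5,100,20,6.4,HCC
13,Yes,49,30,5,48,9.6,8,LM
14,No,84,50,5,100,20,7.3,LM
15,No,54,50,5,100,20,2.5,HCC
16,Yes,72,60,5,132,26.4,2.4,LM
17,No,87,54,3,151.2,50.4,1.8,LM
18,No,59,30,3,60,20,2.7,HCC
19,Yes,50,50,5,100,20,4.8,LM
20,No,72,60,5,132,26.4,3.3,LM
21,No,71,50,5,100,20,1.7,LM
22,No,91,50,5,100,20,4.7,ICC
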