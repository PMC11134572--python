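population,allele,carrier_percent,total_n
Japanese,DRB1*01:01,13.51,5000
Japanese,DRB1*01:03,0.00,5000
Japanese,DRB1*01:04,0.00,5000
Japanese,DRB1*03:01,0.72,5000
Japanese,DRB1*04:01,2.28,5000
Japanese,DRB1*04:04,12.23,5000
Japanese,DRB1*04:05,25.70,5000
Japanese,DRB1*04:08,0.92,5000
Japanese,DRB1*04:10,3.80,5000
Japanese,DRB1*07:01,0.41,5000
Japanese,DRB1*08:01,16.78,5000
Japanese,DRB1*08:02,7.38,5000
Japanese,DRB1*08:73,3.02,5000
Japanese,DRB1*09:01,28.77,5000
Japanese,DRB1*11:01,4.00,5000
Japanese,DRB1*11:02,0.20,5000
Japanese,DRB1*11:04,4.09,5000
Japanese,DRB1*11:58,2.40,5000
Japanese,DRB1*12:01,8.93,5000
Japanese,DRB1*13:01,1.22,5000
Japanese,DRB1*13:02,12.49,5000
Japanese,DRB1*13:03,0.00,5000
Japanese,DRB1*14:01,5.10,5000
Japanese,DRB1*15:01,13.99,5000
Japanese,DRB1*15:02,22.89,5000
Japanese,DRB1*16:01,1.53,5000
Caucasian,DRB1*01:01,15.02,20000
Caucasian,DRB1*01:03,1.96,20000
Caucasian,DRB1*01:04,4.02,20000
Caucasian,DRB1*03:01,29.04,20000
Caucasian,DRB1*04:01,7.82,20000
Caucasian,DRB1*04:04,8.41,20000
Caucasian,DRB1*04:05,6.54,20000
Caucasian,DRB1*04:08,1.94,20000
Caucasian,DRB1*04:10,0.09,20000
Caucasian,DRB1*07:01,24.05,20000
Caucasian,DRB1*08:01,3.98,20000
Caucasian,DRB1*08:02,0.34,20000
Caucasian,DRB1*08:73,0.01,20000
Caucasian,DRB1*09:01,0.71,20000
Caucasian,DRB1*11:01,11.47,20000
Caucasian,DRB1*11:02,6.60,20000
Caucasian,DRB1*11:04,8.29,20000
Caucasian,DRB1*11:58,0.03,20000
Caucasian,DRB1*12:01,2.58,20000
Caucasian,DRB1*13:01,11.39,20000
Caucasian,DRB1*13:02,7.28,20000
Caucasian,DRB1*13:03,2.58,20000
Caucasian,DRB1*14:01,4.83,20000
Caucasian,DRB1*15:01,16.04,20000
Caucasian,DRB1*15:02,1.86,20000
Caucasian,DRB1*16:01,6.98,20000
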