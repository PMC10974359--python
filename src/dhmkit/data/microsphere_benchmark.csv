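data_number,ssim_unfiltered,ssim_gaussian,ssim_proposed,psnr_unfiltered,psnr_gaussian,psnr_proposed
1,0.7144,0.7301,0.7429,8.844,8.923,9.556
2,0.7258,0.7306,0.7345,8.626,8.827,8.856
3,0.7194,0.7269,0.7375,8.677,8.941,8.996
4,0.7188,0.7233,0.7341,9.181,9.369,9.408
5,0.7196,0.7243,0.7368,8.587,9.113,9.314
6,0.7264,0.7298,0.7368,8.202,8.804,8.927
7,0.8186,0.8232,0.8349,8.945,9.135,9.265
8,0.7749,0.7986,0.8241,9.235,9.352,9.399
9,0.7956,0.8199,0.8254,8.658,8.843,9.026
10,0.7750,0.7964,0.8197,8.653,8.921,9.190
11,0.8011,0.8254,0.8346,9.053,9.124,9.265
12,0.7988,0.8027,0.8146,8.657,8.862,9.035
13,0.7747,0.7835,0.7899,8.674,9.024,9.352
14,0.8334,0.8372,0.8456,8.399,8.923,9.068
15,0.7684,0.7797,0.7854,9.156,9.284,9.305
16,0.7328,0.7597,0.7863,8.355,8.659,8.953
17,0.7155,0.7358,0.7446,8.851,9.025,9.278
18,0.7119,0.7255,0.7298,9.014,9.208,9.293
19,0.7615,0.7862,0.7913,8.676,8.933,9.019
20,0.8143,0.8220,0.8301,8.443,8.952,9.108
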