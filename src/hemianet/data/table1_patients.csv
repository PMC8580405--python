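id,group,lesion_age_months,hrp_black_pre,hrp_gray_pre,hrp_white_pre,hrp_black_post,hrp_gray_post,hrp_white_post,hrp_black_fu,hrp_gray_fu,hrp_white_fu,rt_gray_pre,rt_white_pre,rt_gray_post,rt_white_post,rt_gray_fu,rt_white_fu,fov_pre,fov_post,fov_fu,gender,age_years
1,2,45,181,29,231,182,28,231,180,33,228,0.50,0.43,0.49,0.43,0.53,0.42,24,25,25,M,24
2,2,61,109,41,291,112,36,293,117,23,301,0.52,0.41,0.52,0.43,0.43,0.42,26,26,25,M,44
3,0,20,60,5,376,56,14,371,55,13,373,0.44,0.35,0.38,0.34,0.42,0.35,26,26,26,M,55
4,0,45,145,65,231,123,92,226,122,85,234,0.47,0.42,0.52,0.46,0.52,0.46,21,20,20,F,75
5,1,19,208,71,162,214,69,158,205,60,176,0.55,0.48,0.55,0.48,0.60,0.48,26,26,26,M,65
6,2,28,125,24,292,115,33,293,110,33,298,0.50,0.39,0.49,0.39,0.50,0.38,28,27,28,M,53
7,1,117,194,8,239,188,16,237,191,23,227,0.49,0.39,0.52,0.39,0.48,0.43,28,28,27,M,61
8,1,29,98,48,295,103,51,287,92,79,270,0.49,0.40,0.48,0.42,0.50,0.43,27,27,27,M,56
9,0,25,149,13,279,150,13,278,149,19,273,0.50,0.38,0.53,0.38,0.46,0.38,27,27,27,M,68
10,1,156,176,19,246,176,15,250,177,16,248,0.51,0.42,0.49,0.41,0.50,0.42,24,27,27,M,51
11,1,21,133,109,199,133,117,191,157,73,211,0.48,0.43,0.53,0.40,0.54,0.41,23,23,24,M,66
12,2,11,198,14,229,198,7,236,193,18,230,0.53,0.48,0.53,0.48,0.53,0.49,27,28,29,M,62
13,0,49,170,79,192,179,39,223,180,56,205,0.45,0.39,0.51,0.41,0.54,0.45,23,27,27,F,48
14,0,27,164,128,149,138,141,162,162,123,156,0.55,0.44,0.54,0.45,0.53,0.45,26,25,25,F,55
15,2,25,186,21,234,176,31,234,177,27,237,0.51,0.37,0.50,0.36,0.51,0.37,28,29,29,F,60
16,2,19,151,34,256,133,45,263,145,32,264,0.60,0.46,0.54,0.43,0.57,0.44,24,24,24,M,50
17,0,12,48,120,273,16,91,334,47,76,318,0.50,0.42,0.50,0.41,0.56,0.43,26,29,26,M,68
18,1,43,199,30,212,202,21,218,200,27,214,0.53,0.36,0.48,0.36,0.50,0.36,21,23,25,F,54
19,2,93,170,16,255,170,6,265,172,4,265,0.52,0.44,0.49,0.38,0.58,0.39,25,27,27,M,67
20,1,6,282,28,131,283,26,132,287,25,129,0.52,0.47,0.56,0.48,0.56,0.49,26,26,26,M,53
21,0,106,194,19,228,191,14,236,193,19,229,0.62,0.53,0.63,0.56,0.63,0.54,22,24,24,M,59
22,1,9,203,12,226,199,10,232,206,9,226,0.55,0.45,0.60,0.45,0.57,0.48,29,29,27,M,57
23,0,7,227,58,156,246,59,136,248,54,139,0.66,0.65,0.74,0.72,0.75,0.72,26,25,24,F,72
24,2,10,159,68,214,177,88,176,160,88,193,0.55,0.42,0.54,0.43,0.54,0.43,27,28,28,M,54
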