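# gaitmanifold Fourier trajectory, T=1.135
joint,a0,a1,a2,a3,a4,a5,a6,a7,a8,b1,b2,b3,b4,b5,b6,b7,b8
ankle_l,0.25059558816959959,-0.26536898593129232,-0.13661863380889772,-0.051438059943774248,0.032790240714896203,0.00094455457959146587,-0.00052653438312175182,0.0085624990484629709,0.003236588906267691,-0.1197308144050804,-0.05695555006234844,0.093624646893497809,0.014632542019561566,-0.0046258771334319639,0.012377641084074603,0.0080890027803009919,0.0075279235956933338
knee_l,-0.57509196926400441,0.11172706971097285,0.17665653905571291,0.14122745014344934,-0.02448223773584135,0.0094168419165255556,0.0072223445304360444,-0.0072330117552596726,0.0038233695389188927,0.16300706100928836,0.09327594227732218,-0.10184414859822502,-0.069290943730401816,0.0079783417187329446,-0.026318576175171665,-0.0079064362402260814,-0.007395215226617167
hip_l,0.28799638121923599,0.30217256898976458,-0.028824860376785645,-0.099344618927981132,0.00078793062838017857,-0.0034928553692850496,-0.00041910296715130064,0.0048454136553095608,-0.0035501362284661329,0.0086629831466485674,-0.15142885578308957,0.020587306545118741,0.041429084522083978,0.00032939620261142842,0.013341269722619209,0.00095064096128315929,0.0020916215425164312
ankle_r,0.25059558816959959,0.26536898593129232,-0.13661863380889772,0.051438059943774248,0.032790240714896203,-0.00094455457959146587,-0.00052653438312175182,-0.0085624990484629709,0.003236588906267691,0.1197308144050804,-0.05695555006234844,-0.093624646893497809,0.014632542019561566,0.0046258771334319639,0.012377641084074603,-0.0080890027803009919,0.0075279235956933338
knee_r,-0.57509196926400441,-0.11172706971097285,0.17665653905571291,-0.14122745014344934,-0.02448223773584135,-0.0094168419165255556,0.0072223445304360444,0.0072330117552596726,0.0038233695389188927,-0.16300706100928836,0.09327594227732218,0.10184414859822502,-0.069290943730401816,-0.0079783417187329446,-0.026318576175171665,0.0079064362402260814,-0.007395215226617167
hip_r,0.28799638121923599,-0.30217256898976458,-0.028824860376785645,0.099344618927981132,0.00078793062838017857,0.0034928553692850496,-0.00041910296715130064,-0.0048454136553095608,-0.0035501362284661329,-0.0086629831466485674,-0.15142885578308957,-0.020587306545118741,0.041429084522083978,-0.00032939620261142842,0.013341269722619209,-0.00095064096128315929,0.0020916215425164312
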