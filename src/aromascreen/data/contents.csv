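compound_id,cultivar,replicate,content
F1,CV1,1,109
F1,CV2,1,53.2
F1,CV3,1,71.6
F1,CV4,1,63.6
F2,CV1,1,200
F2,CV2,1,112
F2,CV3,1,199
F2,CV4,1,158
F3,CV1,1,30.2
F3,CV2,1,37.1
F3,CV3,1,38.2
F3,CV4,1,36.2
F4,CV1,1,23.4
F4,CV2,1,25.4
F4,CV3,1,15.5
F4,CV4,1,23.2
F5,CV1,1,48.1
F5,CV2,1,43.1
F5,CV3,1,63.5
F5,CV4,1,47.2
F6,CV1,1,23.7
F6,CV2,1,n.d.
F6,CV3,1,7.72
F6,CV4,1,26.9
F7,CV1,1,4.08
F7,CV2,1,3.38
F7,CV3,1,2.54
F7,CV4,1,5.12
F8,CV1,1,180
F8,CV2,1,166
F8,CV3,1,360
F8,CV4,1,160
F9,CV1,1,22.4
F9,CV2,1,29.8
F9,CV3,1,17.2
F9,CV4,1,25.4
F10,CV1,1,559
F10,CV2,1,536
F10,CV3,1,619
F10,CV4,1,587
F11,CV1,1,53.6
F11,CV2,1,45.5
F11,CV3,1,95.6
F11,CV4,1,13.2
F12,CV1,1,138
F12,CV2,1,56.4
F12,CV3,1,44.3
F12,CV4,1,12.3
F13,CV1,1,n.d.
F13,CV2,1,n.d.
F13,CV3,1,n.d.
F13,CV4,1,6.84
F14,CV1,1,47.4
F14,CV2,1,113
F14,CV3,1,69.4
F14,CV4,1,n.d.
F15,CV1,1,3.98
F15,CV2,1,2.43
F15,CV3,1,6.99
F15,CV4,1,4.06
F16,CV1,1,598
F16,CV2,1,1630
F16,CV3,1,3900
F16,CV4,1,3870
F17,CV1,1,696
F17,CV2,1,n.d.
F17,CV3,1,399
F17,CV4,1,n.d.
F18,CV1,1,n.d.
F18,CV2,1,4.33
F18,CV3,1,4.52
F18,CV4,1,n.d.
F19,CV1,1,n.d.
F19,CV2,1,1.53
F19,CV3,1,n.d.
F19,CV4,1,n.d.
F20,CV1,1,n.d.
F20,CV2,1,n.d.
F20,CV3,1,2.75
F20,CV4,1,n.d.
F21,CV1,1,6.13
F21,CV2,1,6.87
F21,CV3,1,n.d.
F21,CV4,1,n.d.
F22,CV1,1,3.63
F22,CV2,1,n.d.
F22,CV3,1,3.09
F22,CV4,1,n.d.
F23,CV1,1,n.d.
F23,CV2,1,n.d.
F23,CV3,1,n.d.
F23,CV4,1,1.21
F24,CV1,1,126
F24,CV2,1,157
F24,CV3,1,245
F24,CV4,1,197
F25,CV1,1,4.78
F25,CV2,1,n.d.
F25,CV3,1,1.23
F25,CV4,1,n.d.
F26,CV1,1,1.80
F26,CV2,1,n.d.
F26,CV3,1,n.d.
F26,CV4,1,3.71
F27,CV1,1,n.d.
F27,CV2,1,n.d.
F27,CV3,1,n.d.
F27,CV4,1,1.42
F28,CV1,1,24.2
F28,CV2,1,44.1
F28,CV3,1,50.8
F28,CV4,1,59.7
F29,CV1,1,n.d.
F29,CV2,1,n.d.
F29,CV3,1,20.2
F29,CV4,1,10.4
F30,CV1,1,3.15
F30,CV2,1,n.d.
F30,CV3,1,9.35
F30,CV4,1,14.8
F31,CV1,1,12.3
F31,CV2,1,7.83
F31,CV3,1,10.1
F31,CV4,1,21.1
F32,CV1,1,12.4
F32,CV2,1,12.7
F32,CV3,1,28.1
F32,CV4,1,64.8
F33,CV1,1,n.d.
F33,CV2,1,n.d.
F33,CV3,1,n.d.
F33,CV4,1,4.73
F34,CV1,1,n.d.
F34,CV2,1,n.d.
F34,CV3,1,n.d.
F34,CV4,1,1.57
F35,CV1,1,3.65
F35,CV2,1,1.96
F35,CV3,1,n.d.
F35,CV4,1,n.d.
F36,CV1,1,n.d.
F36,CV2,1,2.60
F36,CV3,1,n.d.
F36,CV4,1,6.74
F37,CV1,1,13.6
F37,CV2,1,18.3
F37,CV3,1,8.9
F37,CV4,1,22.6
F38,CV1,1,n.d.
F38,CV2,1,5.44
F38,CV3,1,n.d.
F38,CV4,1,3.00
F39,CV1,1,13.7
F39,CV2,1,48.4
F39,CV3,1,40.5
F39,CV4,1,64.1
F40,CV1,1,n.d.
F40,CV2,1,5.49
F40,CV3,1,n.d.
F40,CV4,1,n.d.
F41,CV1,1,n.d.
F41,CV2,1,n.d.
F41,CV3,1,2.30
F41,CV4,1,18.6
F42,CV1,1,136.4
F42,CV2,1,183.1
F42,CV3,1,88.9
F42,CV4,1,225.8
F43,CV1,1,1.44
F43,CV2,1,1.37
F43,CV3,1,1.36
F43,CV4,1,1.42
F44,CV1,1,n.d.
F44,CV2,1,143
F44,CV3,1,n.d.
F44,CV4,1,n.d.
F45,CV1,1,n.d.
F45,CV2,1,11.6
F45,CV3,1,9.45
F45,CV4,1,7.08
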