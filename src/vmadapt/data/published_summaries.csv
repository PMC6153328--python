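experiment,context,feedback,measure,group,n,mean,sd
exp1,horizontal,endpoint,target_error,CB,16,-1.00,4.11
exp1,horizontal,endpoint,target_error,PFC,15,1.41,2.51
exp1,horizontal,endpoint,target_error,SHAM,15,-3.94,8.53
exp1,horizontal,endpoint,explicit,CB,16,29.42,5.78
exp1,horizontal,endpoint,explicit,PFC,15,33.35,6.37
exp1,horizontal,endpoint,explicit,SHAM,15,28.73,8.09
exp1,horizontal,endpoint,implicit,CB,16,15.29,5.48
exp1,horizontal,endpoint,implicit,PFC,15,12.79,5.86
exp1,horizontal,endpoint,implicit,SHAM,15,13.41,5.74
exp2,vertical,online,target_error,CB,10,-2.67,4.20
exp2,vertical,online,target_error,PFC,10,-4.79,5.01
exp2,vertical,online,target_error,SHAM,9,-6.61,5.44
exp2,vertical,online,explicit,CB,10,10.15,11.36
exp2,vertical,online,explicit,PFC,10,17.26,6.33
exp2,vertical,online,explicit,SHAM,9,15.56,11.99
exp2,vertical,online,implicit,CB,10,31.25,8.40
exp2,vertical,online,implicit,PFC,10,22.84,6.84
exp2,vertical,online,implicit,SHAM,9,23.10,10.84
exp3_horizontal,horizontal,online,target_error,CB,10,-1.28,3.31
exp3_horizontal,horizontal,online,target_error,PFC,10,-2.40,2.29
exp3_horizontal,horizontal,online,target_error,SHAM,9,-1.45,2.03
exp3_horizontal,horizontal,online,explicit,CB,10,26.55,8.65
exp3_horizontal,horizontal,online,explicit,PFC,10,25.10,9.91
exp3_horizontal,horizontal,online,explicit,SHAM,9,22.48,6.81
exp3_horizontal,horizontal,online,implicit,CB,10,17.05,7.13
exp3_horizontal,horizontal,online,implicit,PFC,10,17.26,9.56
exp3_horizontal,horizontal,online,implicit,SHAM,9,20.98,6.46
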