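experiment,analysis,measure,pair,statistic,value
exp1,anova,target_error,,F,3.40
exp1,anova,target_error,,eta_p_sq,0.14
exp1,anova,target_error,,cohens_f,0.40
exp1,anova,target_error,,bf10,1.65
exp1,anova,explicit,,F,2.03
exp1,anova,explicit,,eta_p_sq,0.086
exp1,anova,explicit,,cohens_f,0.31
exp1,anova,explicit,,bf10,0.66
exp1,anova,implicit,,F,0.82
exp1,anova,implicit,,eta_p_sq,0.037
exp1,anova,implicit,,cohens_f,0.20
exp1,anova,implicit,,bf10,0.29
exp1,tukey,target_error,CB-PFC,p,0.46
exp1,tukey,target_error,CB-PFC,cohens_d,0.71
exp1,tukey,target_error,CB-PFC,hedges_g,0.68
exp1,tukey,target_error,CB-SHAM,p,0.32
exp1,tukey,target_error,CB-SHAM,cohens_d,0.44
exp1,tukey,target_error,CB-SHAM,hedges_g,0.43
exp1,tukey,target_error,PFC-SHAM,p,0.033
exp1,tukey,target_error,PFC-SHAM,cohens_d,0.85
exp1,tukey,target_error,PFC-SHAM,hedges_g,0.83
exp1,ttest,explicit,CB-SHAM,t,0.27
exp1,ttest,explicit,CB-SHAM,cohens_d,0.10
exp1,ttest,explicit,CB-SHAM,hedges_g,0.10
exp1,ttest,explicit,PFC-SHAM,t,1.74
exp1,ttest,explicit,PFC-SHAM,cohens_d,0.63
exp1,ttest,explicit,PFC-SHAM,hedges_g,0.62
exp1,ttest,implicit,CB-SHAM,t,0.94
exp1,ttest,implicit,CB-SHAM,cohens_d,0.34
exp1,ttest,implicit,CB-SHAM,hedges_g,0.33
exp1,ttest,implicit,PFC-SHAM,t,-0.29
exp1,ttest,implicit,PFC-SHAM,cohens_d,0.11
exp1,ttest,implicit,PFC-SHAM,hedges_g,0.10
exp2,anova,target_error,,F,1.55
exp2,anova,target_error,,eta_p_sq,0.11
exp2,anova,target_error,,cohens_f,0.35
exp2,anova,target_error,,bf10,0.57
exp2,anova,explicit,,F,1.33
exp2,anova,explicit,,eta_p_sq,0.09
exp2,anova,explicit,,cohens_f,0.31
exp2,anova,explicit,,bf10,0.50
exp2,anova,implicit,,F,2.93
exp2,anova,implicit,,eta_p_sq,0.18
exp2,anova,implicit,,cohens_f,0.47
exp2,anova,implicit,,bf10,1.31
exp2,ttest,target_error,CB-SHAM,t,1.78
exp2,ttest,target_error,CB-SHAM,cohens_d,0.81
exp2,ttest,target_error,CB-SHAM,hedges_g,0.78
exp2,ttest,target_error,PFC-SHAM,t,0.76
exp2,ttest,target_error,PFC-SHAM,cohens_d,0.35
exp2,ttest,target_error,PFC-SHAM,hedges_g,0.33
exp2,ttest,explicit,CB-SHAM,t,-1.01
exp2,ttest,explicit,CB-SHAM,cohens_d,0.46
exp2,ttest,explicit,CB-SHAM,hedges_g,0.44
exp2,ttest,explicit,PFC-SHAM,t,0.39
exp2,ttest,explicit,PFC-SHAM,cohens_d,0.18
exp2,ttest,explicit,PFC-SHAM,hedges_g,0.17
exp2,ttest,implicit,CB-SHAM,t,1.84
exp2,ttest,implicit,CB-SHAM,cohens_d,0.84
exp2,ttest,implicit,CB-SHAM,hedges_g,0.81
exp2,ttest,implicit,PFC-SHAM,cohens_d,0.03
exp2,ttest,implicit,PFC-SHAM,hedges_g,0.03
exp3a,ttest,target_error,HOR-VER,t,2.66
exp3a,ttest,target_error,HOR-VER,cohens_d,1.26
exp3a,ttest,target_error,HOR-VER,hedges_g,1.20
exp3a,ttest,explicit,HOR-VER,t,1.50
exp3a,ttest,explicit,HOR-VER,cohens_d,0.71
exp3a,ttest,explicit,HOR-VER,hedges_g,0.68
exp3a,ttest,implicit,HOR-VER,t,-0.50
exp3a,ttest,implicit,HOR-VER,cohens_d,0.24
exp3a,ttest,implicit,HOR-VER,hedges_g,0.23
exp3b,factorial,target_error,interaction,F,1.16
exp3b,factorial,target_error,interaction,eta_p_sq,0.04
exp3b,factorial,target_error,interaction,cohens_f,0.20
exp3b,factorial,target_error,context,F,8.34
exp3b,factorial,target_error,context,eta_p_sq,0.14
exp3b,factorial,target_error,context,cohens_f,0.40
exp3b,factorial,target_error,stim,F,1.48
exp3b,factorial,target_error,stim,eta_p_sq,0.05
exp3b,factorial,target_error,stim,cohens_f,0.23
exp3b,factorial,explicit,interaction,F,1.51
exp3b,factorial,explicit,interaction,eta_p_sq,0.06
exp3b,factorial,explicit,interaction,cohens_f,0.25
exp3b,factorial,explicit,context,F,17.62
exp3b,factorial,explicit,context,eta_p_sq,0.25
exp3b,factorial,explicit,context,cohens_f,0.58
exp3b,factorial,explicit,stim,F,0.49
exp3b,factorial,explicit,stim,eta_p_sq,0.02
exp3b,factorial,explicit,stim,cohens_f,0.14
exp3b,factorial,implicit,interaction,F,2.68
exp3b,factorial,implicit,interaction,eta_p_sq,0.09
exp3b,factorial,implicit,interaction,cohens_f,0.31
exp3b,factorial,implicit,context,F,11.09
exp3b,factorial,implicit,context,eta_p_sq,0.18
exp3b,factorial,implicit,context,cohens_f,0.47
exp3b,factorial,implicit,stim,F,1.21
exp3b,factorial,implicit,stim,eta_p_sq,0.05
exp3b,factorial,implicit,stim,cohens_f,0.23
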