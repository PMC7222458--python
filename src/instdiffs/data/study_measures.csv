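name,group,causal_rank,reliability,in_path_model
Hist_Size,institutional history,101,0.925,1
Hist_GP,institutional history,102,0.968,1
Hist_Female,institutional history,103,0.831,1
Hist_Psyc,institutional history,104,0.736,0
Hist_Anaes,institutional history,105,0.716,0
Hist_OG,institutional history,106,0.584,0
Hist_IntMed,institutional history,107,0.945,0
Hist_Surgery,institutional history,108,0.634,0
Post2000,institutional history,109,,1
REF,institutional history,110,0.691,1
PBL_School,curricular influences,201,,1
Spend_Student,curricular influences,202,0.843,1
Student_Staff,curricular influences,203,0.835,1
Entrants_N,curricular influences,204,0.994,1
Entrants_Female,selection,301,0.903,1
Entrants_NonHome,selection,302,0.958,1
EntryGrades,selection,303,0.907,1
Teach_Factor1_Trad,teaching/learning/assessment,401,,1
Teach_Factor2_Struc,teaching/learning/assessment,402,,1
Teach_GP,teaching/learning/assessment,403,,1
Teach_Psyc,teaching/learning/assessment,404,,0
Teach_Anaes,teaching/learning/assessment,405,,0
Teach_OG,teaching/learning/assessment,406,,0
Teach_IntMed,teaching/learning/assessment,407,,0
Teach_Surgery,teaching/learning/assessment,408,,0
ExamTime,teaching/learning/assessment,409,,1
SelfRegLearn,teaching/learning/assessment,410,,1
NSS_Satis'n,student satisfaction,501,0.817,1
NSS_Feedback,student satisfaction,502,0.820,1
UKFPO_EPM,Foundation entry scores,601,0.890,1
UKFPO_SJT,Foundation entry scores,602,0.937,1
F1_Preparedness,F1 perceptions,701,0.904,1
F1_Satis'n,F1 perceptions,702,0.792,1
F1_Workload,F1 perceptions,703,0.792,1
F1_Superv'n,F1 perceptions,704,0.792,1
Trainee_GP,specialty training choice,801,0.779,1
Trainee_Psyc,specialty training choice,802,0.470,0
TraineeApp_Surgery,specialty training choice,803,0.794,0
TraineeApp_Anaes,specialty training choice,804,,0
GMC_PGexams,postgraduate examination performance,901,,1
MRCGP_AKT,postgraduate examination performance,902,0.970,0
MRCGP_CSA,postgraduate examination performance,903,0.919,0
FRCA_Pt1,postgraduate examination performance,904,,0
MRCOG_Pt1,postgraduate examination performance,905,,0
MRCOG_Pt2,postgraduate examination performance,906,,0
MRCP_Pt1,postgraduate examination performance,907,0.977,0
MRCP_Pt2,postgraduate examination performance,908,0.941,0
MRCP_PACES,postgraduate examination performance,909,0.857,0
GMC_Sanctions,fitness to practise,1001,0.691,1
ARCP_NonExam,fitness to practise,1002,,1
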