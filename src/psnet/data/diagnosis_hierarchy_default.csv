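category_rank,category_name,icd10_prefix
0,excluded,F17
0,excluded,P96.1
0,excluded,Q86.0
1,schizophrenia_psychotic,F20
1,schizophrenia_psychotic,F21
1,schizophrenia_psychotic,F22
1,schizophrenia_psychotic,F23
1,schizophrenia_psychotic,F24
1,schizophrenia_psychotic,F25
1,schizophrenia_psychotic,F26
1,schizophrenia_psychotic,F27
1,schizophrenia_psychotic,F28
1,schizophrenia_psychotic,F29
2,bipolar,F30
2,bipolar,F31
3,depression_mood,F32
3,depression_mood,F33
3,depression_mood,F34
3,depression_mood,F35
3,depression_mood,F36
3,depression_mood,F37
3,depression_mood,F38
3,depression_mood,F39
4,anxiety_stress,F40
4,anxiety_stress,F41
4,anxiety_stress,F42
4,anxiety_stress,F43
4,anxiety_stress,F44
4,anxiety_stress,F45
4,anxiety_stress,F46
4,anxiety_stress,F47
4,anxiety_stress,F48
5,other_mental,F01
5,other_mental,F02
5,other_mental,F03
5,other_mental,F04
5,other_mental,F05
5,other_mental,F06
5,other_mental,F07
5,other_mental,F08
5,other_mental,F09
5,other_mental,F50
5,other_mental,F51
5,other_mental,F52
5,other_mental,F53
5,other_mental,F54
5,other_mental,F55
5,other_mental,F56
5,other_mental,F57
5,other_mental,F58
5,other_mental,F59
5,other_mental,F60
5,other_mental,F61
5,other_mental,F62
5,other_mental,F63
5,other_mental,F64
5,other_mental,F65
5,other_mental,F66
5,other_mental,F67
5,other_mental,F68
5,other_mental,F69
5,other_mental,F70
5,other_mental,F71
5,other_mental,F72
5,other_mental,F73
5,other_mental,F74
5,other_mental,F75
5,other_mental,F76
5,other_mental,F77
5,other_mental,F78
5,other_mental,F79
5,other_mental,F80
5,other_mental,F81
5,other_mental,F82
5,other_mental,F83
5,other_mental,F84
5,other_mental,F85
5,other_mental,F86
5,other_mental,F87
5,other_mental,F88
5,other_mental,F89
5,other_mental,F90
5,other_mental,F91
5,other_mental,F92
5,other_mental,F93
5,other_mental,F94
5,other_mental,F95
5,other_mental,F96
5,other_mental,F97
5,other_mental,F98
5,other_mental,F99
6,substance_use,F10
6,substance_use,F11
6,substance_use,F12
6,substance_use,F13
6,substance_use,F14
6,substance_use,F15
6,substance_use,F16
6,substance_use,F18
6,substance_use,F19
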