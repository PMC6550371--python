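expert_id,arm,question_id,threshold_mm,probability_pct
expert_01,pamidronate,QP1,60,75
expert_01,pamidronate,QP2,30,50
expert_01,pamidronate,QP3,20,40
expert_01,pamidronate,QP4,10,5
expert_01,pamidronate,QP5,5,0
expert_01,adalimumab,QA1,60,80
expert_01,adalimumab,QA2,30,40
expert_01,adalimumab,QA3,20,35
expert_01,adalimumab,QA4,10,5
expert_01,adalimumab,QA5,5,0
expert_02,pamidronate,QP1,60,85
expert_02,pamidronate,QP2,30,25
expert_02,pamidronate,QP3,20,15
expert_02,pamidronate,QP4,10,10
expert_02,pamidronate,QP5,5,5
expert_02,adalimumab,QA1,60,80
expert_02,adalimumab,QA2,30,30
expert_02,adalimumab,QA3,20,25
expert_02,adalimumab,QA4,10,20
expert_02,adalimumab,QA5,5,15
expert_03,pamidronate,QP1,60,80
expert_03,pamidronate,QP2,30,40
expert_03,pamidronate,QP3,20,30
expert_03,pamidronate,QP4,10,20
expert_03,pamidronate,QP5,5,10
expert_03,adalimumab,QA1,60,70
expert_03,adalimumab,QA2,30,50
expert_03,adalimumab,QA3,20,40
expert_03,adalimumab,QA4,10,30
expert_03,adalimumab,QA5,5,20
expert_04,pamidronate,QP1,60,90
expert_04,pamidronate,QP2,30,40
expert_04,pamidronate,QP3,20,30
expert_04,pamidronate,QP4,10,20
expert_04,pamidronate,QP5,5,10
expert_04,adalimumab,QA1,60,85
expert_04,adalimumab,QA2,30,45
expert_04,adalimumab,QA3,20,35
expert_04,adalimumab,QA4,10,25
expert_04,adalimumab,QA5,5,15
expert_05,pamidronate,QP1,60,90
expert_05,pamidronate,QP2,30,35
expert_05,pamidronate,QP3,20,25
expert_05,pamidronate,QP4,10,20
expert_05,pamidronate,QP5,5,15
expert_05,adalimumab,QA1,60,75
expert_05,adalimumab,QA2,30,45
expert_05,adalimumab,QA3,20,35
expert_05,adalimumab,QA4,10,25
expert_05,adalimumab,QA5,5,20
expert_06,pamidronate,QP1,60,95
expert_06,pamidronate,QP2,30,40
expert_06,pamidronate,QP3,20,20
expert_06,pamidronate,QP4,10,5
expert_06,pamidronate,QP5,5,2
expert_06,adalimumab,QA1,60,75
expert_06,adalimumab,QA2,30,60
expert_06,adalimumab,QA3,20,40
expert_06,adalimumab,QA4,10,15
expert_06,adalimumab,QA5,5,5
expert_07,pamidronate,QP1,60,85
expert_07,pamidronate,QP2,30,40
expert_07,pamidronate,QP3,20,30
expert_07,pamidronate,QP4,10,20
expert_07,pamidronate,QP5,5,10
expert_07,adalimumab,QA1,60,75
expert_07,adalimumab,QA2,30,50
expert_07,adalimumab,QA3,20,40
expert_07,adalimumab,QA4,10,30
expert_07,adalimumab,QA5,5,10
expert_08,pamidronate,QP1,60,90
expert_08,pamidronate,QP2,30,50
expert_08,pamidronate,QP3,20,40
expert_08,pamidronate,QP4,10,30
expert_08,pamidronate,QP5,5,20
expert_08,adalimumab,QA1,60,95
expert_08,adalimumab,QA2,30,50
expert_08,adalimumab,QA3,20,35
expert_08,adalimumab,QA4,10,20
expert_08,adalimumab,QA5,5,10
expert_09,pamidronate,QP1,60,90
expert_09,pamidronate,QP2,30,40
expert_09,pamidronate,QP3,20,30
expert_09,pamidronate,QP4,10,20
expert_09,pamidronate,QP5,5,10
expert_09,adalimumab,QA1,60,95
expert_09,adalimumab,QA2,30,35
expert_09,adalimumab,QA3,20,25
expert_09,adalimumab,QA4,10,15
expert_09,adalimumab,QA5,5,5
expert_10,pamidronate,QP1,60,90
expert_10,pamidronate,QP2,30,65
expert_10,pamidronate,QP3,20,30
expert_10,pamidronate,QP4,10,20
expert_10,pamidronate,QP5,5,10
expert_10,adalimumab,QA1,60,95
expert_10,adalimumab,QA2,30,60
expert_10,adalimumab,QA3,20,30
expert_10,adalimumab,QA4,10,20
expert_10,adalimumab,QA5,5,10
expert_11,pamidronate,QP1,60,80
expert_11,pamidronate,QP2,30,50
expert_11,pamidronate,QP3,20,20
expert_11,pamidronate,QP4,10,5
expert_11,pamidronate,QP5,5,0
expert_11,adalimumab,QA1,60,80
expert_11,adalimumab,QA2,30,60
expert_11,adalimumab,QA3,20,30
expert_11,adalimumab,QA4,10,20
expert_11,adalimumab,QA5,5,4
expert_12,pamidronate,QP1,60,85
expert_12,pamidronate,QP2,30,40
expert_12,pamidronate,QP3,20,20
expert_12,pamidronate,QP4,10,0
expert_12,pamidronate,QP5,5,0
expert_12,adalimumab,QA1,60,95
expert_12,adalimumab,QA2,30,20
expert_12,adalimumab,QA3,20,10
expert_12,adalimumab,QA4,10,0
expert_12,adalimumab,QA5,5,0
expert_13,pamidronate,QP1,60,60
expert_13,pamidronate,QP2,30,40
expert_13,pamidronate,QP3,20,30
expert_13,pamidronate,QP4,10,25
expert_13,pamidronate,QP5,5,15
expert_13,adalimumab,QA1,60,80
expert_13,adalimumab,QA2,30,15
expert_13,adalimumab,QA3,20,10
expert_13,adalimumab,QA4,10,5
expert_13,adalimumab,QA5,5,0
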