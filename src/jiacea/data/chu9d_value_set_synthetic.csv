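dimension,level,weight
worry,1,0.22
worry,2,0.1925
worry,3,0.165
worry,4,0.1375
worry,5,0.11
sadness,1,0.15
sadness,2,0.1175
sadness,3,0.085
sadness,4,0.0525
sadness,5,0.02
pain,1,0.11
pain,2,0.0775
pain,3,0.045
pain,4,0.0125
pain,5,-0.02
tiredness,1,0.11
tiredness,2,0.09
tiredness,3,0.07
tiredness,4,0.05
tiredness,5,0.03
annoyance,1,0.08
annoyance,2,0.05
annoyance,3,0.02
annoyance,4,-0.01
annoyance,5,-0.04
school,1,0.09
school,2,0.0625
school,3,0.035
school,4,0.0075
school,5,-0.02
sleep,1,0.06
sleep,2,0.0325
sleep,3,0.005
sleep,4,-0.0225
sleep,5,-0.05
daily_routine,1,0.07
daily_routine,2,0.04
daily_routine,3,0.01
daily_routine,4,-0.02
daily_routine,5,-0.05
activities,1,0.13
activities,2,0.1025
activities,3,0.075
activities,4,0.0475
activities,5,0.02
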