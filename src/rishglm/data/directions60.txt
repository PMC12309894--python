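# 60 unit gradient directions (x y z), one per row.
# Generated once by antipodally-symmetric electrostatic repulsion;
# minimum pairwise angular separation 18.3 degrees.
-0.408415632373 -0.752146884439 -0.517176696558
-0.832196372768 -0.357841649388 -0.423554661306
-0.909351347446 0.393515245553 0.135003253351
-0.991432711658 0.070673224381 0.109847501614
-0.962691455647 -0.257341984304 0.083667582360
0.428538338439 -0.885957176572 -0.177298544180
0.117315776827 -0.953519743323 -0.277555593713
-0.467792033270 -0.871532000325 -0.146978182116
0.284668777050 0.804364210835 -0.521499667977
-0.691727743206 0.168726710648 -0.702170938158
-0.038317176669 0.270911769727 -0.961841258730
0.825179963590 0.510559549809 -0.241675347913
0.565992727309 0.266747604072 -0.780062784880
-0.763318893755 0.468148932984 0.445175070038
0.969484143383 0.128624639402 0.208701216737
-0.808999688076 0.374084782454 -0.453409395833
-0.561297705184 0.712418364943 0.421194681171
-0.279628841290 -0.284760735800 0.916907320543
-0.491769531203 -0.030731788529 -0.870182903391
0.732575150236 0.412263137938 -0.541638952028
-0.140560822553 -0.990065333822 -0.003645535088
-0.181323578607 -0.040316483625 -0.982596733655
-0.035401536206 0.794398965123 -0.606363764951
-0.676035783567 -0.735148017948 0.050329027849
-0.474921184685 0.039307413375 0.879150041569
0.723233457438 -0.678121515233 -0.130707982233
-0.956239935420 0.225986498771 -0.185836724791
0.049187030809 0.947852208349 -0.314891770499
-0.890215558417 0.173842239684 0.421064288742
-0.269710072789 0.800574048599 0.535105288094
-0.359633065769 0.712932632653 -0.601989301653
0.670477656657 0.664404483267 0.330191451341
0.144502170674 0.576580148641 -0.804160714574
-0.038965625646 -0.341371196504 -0.939120538704
0.753981765583 0.028927038624 -0.656258122697
-0.648690275406 0.282258454748 0.706775134903
-0.461915876178 0.549760614531 0.695986343289
0.295522871712 -0.890413138844 0.346165674887
-0.205078444544 -0.924637336539 -0.320918412469
-0.624570148364 0.669170160290 -0.402645534372
-0.385705478771 -0.331990137801 -0.860821602917
-0.309877227076 0.326210050969 0.893063887293
-0.820116317859 0.549694058532 -0.158888851705
-0.152649901170 0.034567338354 0.987675608078
0.197673432439 -0.978830620632 0.053064396919
0.556270894446 -0.468101935481 0.686617266016
-0.391813141308 -0.898181450473 0.199380401054
-0.707062295913 -0.195023673213 -0.679726913242
-0.588345036698 -0.704448087117 0.396992456288
-0.548463352511 0.826484394844 -0.126931068028
-0.231358285562 -0.594394732599 -0.770174165731
-0.054853784718 -0.806734399425 -0.588362703684
-0.905000266035 -0.165763159719 0.391787051032
-0.450081690842 -0.567167336516 0.689744651272
0.859710653844 0.496201676438 0.121167190143
-0.583411420834 -0.502164166233 -0.638327709090
-0.371338586891 0.272324925537 -0.887663668749
0.126894687340 -0.598020104102 -0.791372032242
0.185629825264 -0.541416613780 0.820005864793
-0.880598184084 0.022964534976 -0.473306949370
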