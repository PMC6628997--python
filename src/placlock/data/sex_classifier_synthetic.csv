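CpG,Coefficient
(Intercept),0.0
cg00191492,1.0638743844697431
cg00292377,0.4110438192035759
cg00258788,0.9005548879744015
cg00225365,0.35969811146894043
cg00147657,-0.3703257930387871
cg00366913,-0.5699657761199537
cg00128580,-0.23225119916303036
cg00449564,3.332975037073771
cg00214747,-3.844755979862786
cg00182193,6.021421434340438
cg00291387,-0.9368879980986003
cg00351975,-2.960011732480839
cg00420933,0.812563186764103
cg00078390,-1.2456254070311956
cg00393100,4.727577834145407
cg00010453,1.0952059370508944
cg00314506,-4.741758885035327
cg00258813,1.7516425573810297
cg00330508,1.242124671396161
cg00416952,5.89090242393738
cg00155093,0.262073284984975
cg00304553,-4.186227548408608
cg00201338,0.5252315940475375
cg00135795,2.9976938909991526
cg00009827,-2.591193045539992
cg00252835,2.075235397373604
cg00063261,0.3739777080562294
cg00097398,-2.677651358913974
cg00034878,-4.7547337210280975
cg00445403,-1.604803477597974
cg00220243,-6.883100716182088
cg00284481,-0.24954425200544728
cg00263325,-1.0702101438689295
cg00124784,3.2236289215258216
cg00152869,-4.874827677171481
cg00249078,-0.9202200494866838
cg00116807,-2.196258607639552
cg00085862,-0.22081650476696163
cg00380927,5.114984108757726
cg00339498,-2.0463350242158453
cg00141516,-0.9775435729118144
cg00282090,-2.311588091951441
cg00226368,3.7136000226486905
cg00269987,0.49429918343703855
cg00104126,-9.296358849631426
cg00086106,1.4138610260939455
cg00117862,2.417288677097037
cg00022656,0.9456290700389698
cg00107488,-2.5486849470083204
cg00449296,3.7302009794608604
cg00026500,-3.900535708657376
cg00091301,-0.230071593403705
cg00376965,5.994184035897766
cg00336862,1.5758290029389275
cg00281923,-2.223765706486324
cg00281985,-1.8601207007818974
cg00029599,-2.574033809742409
cg00327894,-0.7377802163711672
cg00056983,2.026286887641878
cg00266289,1.0142760605969283
cg00372364,-1.893730901830481
cg00358604,2.1388996603053125
cg00083093,-3.066852673351464
cg00134354,-6.128954822022173
cg00264846,1.5157237680611577
cg00001194,2.132153464836476
cg00232265,1.5402696206175146
cg00322903,2.5181168087715684
cg00397729,-1.7037882830346136
cg00353864,-5.703587022729502
cg00241696,-8.947862909611581
cg00057339,9.709337344827247
cg00169300,0.11471545465008681
cg00098669,0.20020350985501065
cg00291305,2.277006098169073
cg00127486,6.728512340407052
cg00329743,-1.724953660570695
cg00014979,2.8517967406497102
cg00339633,0.11772633034366192
cg00112311,0.7623196354090179
cg00013491,-1.5092916569812387
cg00166513,4.442986374581734
cg00108753,1.2273555180098779
cg00330412,-0.8690158797940828
cg00397931,3.725604355902345
cg00113790,0.07133603590105338
cg00385461,-2.4159924025137656
cg00390318,0.9866876851089458
cg00083459,0.09691878804136185
cg00344982,-4.969000635230377
cg00000802,1.006182980530171
cg00071135,-2.334054586975683
cg00417265,2.465190960322909
cg00367144,5.248457978771432
cg00063609,0.849531709526318
cg00317651,3.2974666525007796
cg00280446,-1.2099687863743678
cg00299259,2.474405865884231
cg00363706,0.598723734292043
cg00090485,3.152217539778169
cg00052465,-2.777110469462094
cg00154187,6.471573266086745
cg00146297,-8.448407164180837
cg00085951,1.3047505083219655
cg00233579,-1.605079799234545
cg00141588,-0.8785193867490758
cg00099909,-6.506219483887576
cg00381292,-4.157005921868513
cg00129085,-0.7557201948690763
cg00307798,-2.677491084896849
cg00160269,7.735334826706378
cg00257686,4.716059609730284
cg00122308,0.7042504074803
cg00286921,-1.2493993309033693
cg00355660,-4.016452072419483
cg00297663,-3.1687656029295908
cg00350326,0.22774039805365276
cg00086643,-4.082011532267674
cg00298507,0.03586578424860627
cg00121182,-2.5994636578639634
cg00394705,3.2509063035696926
cg00380498,-2.2952677461775113
cg00276379,3.9202512674902272
cg00224518,-3.769896782633775
cg00436108,-4.245517500009776
cg00154631,-4.735204228651162
cg00337086,-1.6295479629419143
cg00345676,1.0856620606439131
cg00081359,0.373630301774469
cg00137398,-4.605507830197147
cg00300917,3.107740231873055
cg00125568,-5.04149071203146
cg00318847,0.24104544625059937
cg00216686,1.037699496138524
cg00122685,-0.9367551714247042
cg00239429,-2.8094753299344357
cg00134162,3.011199136907276
cg00126575,2.4520403153435146
cg00403806,3.788528937533336
cg00020141,3.6505635487022734
cg00278386,-2.5424327256036308
cg00273360,-3.300512115679278
cg00119547,6.189793920274519
cg00200924,2.2136349691054105
cg00422698,-3.6553534071021696
cg00200561,-6.668355207109318
cg00086222,0.835544599105357
cg00397794,5.97790748973586
cg00282284,0.837057414453856
cg00362869,7.058873262852982
cg00419293,3.0975079335217015
cg00093684,-1.944149474058327
cg00206066,5.155046035302626
cg00387358,3.581334630646354
cg00181750,1.6993208118130418
cg00330899,2.8731218717715294
cg00059157,-0.4376790414924536
cg00143216,-4.167444198833267
cg00098466,-0.9066398273085371
cg00334044,-0.5970507683202583
cg00377260,-0.7264470668162736
cg00185096,-2.0530271876855957
cg00061921,10.666420616277325
cg00120090,0.045886586418385285
cg00293708,7.3132798273827975
cg00359745,2.974697517817861
cg00182555,2.3441601010045288
cg00234570,1.8928331650636712
cg00370924,1.2287225389870513
cg00083142,3.409670778321323
cg00172828,-1.0178460083790002
cg00044429,-0.5787337567864531
cg00332707,-3.12990804331587
cg00384240,-0.27531923766195526
cg00213336,-5.326400922764347
cg00321066,3.729031006544054
cg00129182,0.7344481844499362
cg00062579,-8.346609771440992
cg00418084,-3.2691230181391644
cg00091103,-7.63379884255329
cg00120496,-0.09960888933479606
cg00173802,4.539252501765655
cg00393964,1.962366021193201
cg00159395,2.878824018977078
cg00121914,-5.112497981404357
cg00437964,2.990944266033314
cg00110399,3.8553274532322597
cg00422269,0.730020232166822
cg00186607,-0.19074677300683332
cg00154521,-1.8014953349725062
cg00295954,0.9813749992630071
cg00284638,3.493357201001634
cg00229714,-3.9927202394338637
cg00044071,-1.9704359130408364
cg00055615,-2.751801700000154
cg00408636,-1.6106410493908054
cg00072051,2.4875571602536763
cg00136481,-0.04613247633093093
cg00343390,1.045035532287491
cg00284396,-3.140890581695478
cg00354936,-1.3236001258396564
cg00057811,8.273373386722769
cg00066909,-4.100082999199138
cg00028142,-1.2295120623742866
cg00297676,-0.34139099439097226
cg00235068,5.301359185129435
cg00349163,6.3760392265781665
cg00324389,-4.50244276763638
cg00117282,2.120262592437871
cg00094973,4.684594341275773
cg00074488,-2.9303529029709163
cg00413288,1.129524662077034
cg00356067,1.5269879449663666
cg00004597,6.43951056631699
cg00119075,-1.4817153644289258
cg00401826,4.258415685918333
cg00340998,-4.561304592887672
cg00430951,-0.6859234679369943
cg00355521,9.371399525091123
cg00079246,-3.4170910200003735
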