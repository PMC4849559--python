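sex,age,qx
male,18,0.00016304316976056832
male,19,0.0001805497307352244
male,20,0.00019993584933442055
male,21,0.00022140327804920368
male,22,0.000245175415942267
male,23,0.0002714996289884253
male,24,0.0003006498186455264
male,25,0.00033292926509753684
male,26,0.0003686737744063029
male,27,0.00040825516188769395
male,28,0.00045208510742766883
male,29,0.0005006194221972571
male,30,0.0005543627703599174
male,31,0.000613873893907324
male,32,0.0006797713937714001
male,33,0.0007527401258651256
male,34,0.0008335382767598043
male,35,0.0009230051903554859
male,36,0.0010220700241989622
male,37,0.0011317613220974687
male,38,0.0012532175984341087
male,39,0.0013876990391585853
male,40,0.0015366004348765783
male,41,0.0017014654728416678
male,42,0.0018840025270348004
male,43,0.002086102098942555
male,44,0.0023098560761812825
male,45,0.002557578991788212
male,46,0.002831831483853464
male,47,0.0031354461732098216
male,48,0.0034715561961119468
male,49,0.0038436266491985727
male,50,0.0042554892254388355
male,51,0.004711380342099725
male,52,0.005215983084814191
male,53,0.005774473315308115
male,54,0.006392570313837886
male,55,0.0070765923503780526
male,56,0.007833517600361883
male,57,0.008671050840392991
male,58,0.009597696375638454
male,59,0.010622837662062512
male,60,0.011756824091377571
male,61,0.013011065402181998
male,62,0.014398134164280152
male,63,0.015931876750966745
male,64,0.01762753316163057
male,65,0.0195018659789018
male,66,0.021573298634089744
male,67,0.023862063003803224
male,68,0.02639035615981411
male,69,0.029182505831949257
male,70,0.032265143806588625
male,71,0.03566738605534314
male,72,0.03942101785134289
male,73,0.04356068146321346
male,74,0.048124063195434164
male,75,0.05315207554187884
male,76,0.05868902900810602
male,77,0.06478278670693194
male,78,0.07148489311004946
male,79,0.07885066631646076
male,80,0.08693924085101135
male,81,0.09581354531644926
male,82,0.10554019618727428
male,83,0.11618928567206877
male,84,0.1278340379338927
male,85,0.14055030414183012
male,86,0.1544158629890543
male,87,0.1695094896943602
male,88,0.18590975345205618
male,89,0.20369350129006702
male,90,0.22293398598108216
male,91,0.24369859785892767
male,92,0.26604616616462107
male,93,0.29002380614283896
male,94,0.31566330498623607
male,95,0.34297706447572407
male,96,0.3719536523981287
male,97,0.40255305995525625
male,98,0.43470181931548146
male,99,0.46828820413960115
male,100,1.0
female,18,9.266686769515697e-05
female,19,0.00010292554519308883
female,20,0.00011431984376453208
female,21,0.00012697545988382686
female,22,0.00014103199922266274
female,23,0.00015664451497232612
female,24,0.0001739852161065647
female,25,0.00019324536431364336
female,26,0.0002146373803796342
female,27,0.00023839718308005242
female,28,0.000264786786161042
female,29,0.0002940971817831928
female,30,0.00032665154189737144
female,31,0.00036280877245009613
female,32,0.0004029674591046195
female,33,0.0004475702473649701
female,34,0.0004971087046273803
female,35,0.0005521287168128719
female,36,0.0006132364779026789
female,37,0.0006811051369527421
female,38,0.0007564821740619898
female,39,0.0008401975843818077
female,40,0.0009331729576261827
female,41,0.001036431549764294
female,42,0.0011511094537052236
female,43,0.0012784679869044524
female,44,0.0014199074260043965
female,45,0.0015769822319574578
female,46,0.0017514179236352012
female,47,0.0019451297737941298
female,48,0.0021602435185107405
female,49,0.002399118289889035
female,50,0.0026643720020287365
female,51,0.0029589094419618656
female,52,0.0032859533405299457
female,53,0.003649078722945287
female,54,0.004052250865003049
female,55,0.004499867208426989
female,56,0.004996803617443701
female,57,0.005548465388048651
female,58,0.006160843451105458
female,59,0.006840576239775853
female,60,0.007595017719978059
female,61,0.008432312108500817
female,62,0.009361475825625742
female,63,0.010392487245786897
female,64,0.011536384818553791
female,65,0.012805374130104519
female,66,0.014212944458615429
female,67,0.015773995340998548
female,68,0.01750497360741532
female,69,0.019424021246922663
female,70,0.021551134333841704
female,71,0.023908333059488807
female,72,0.026519842665160054
female,73,0.029412284744578576
female,74,0.03261487795944773
female,75,0.03615964666917437
female,76,0.04008163529061304
female,77,0.044419125347515465
female,78,0.04921385111014176
female,79,0.05451120842744284
female,80,0.06036044977852262
female,81,0.06681485667580023
female,82,0.07393187829832648
female,83,0.08177322258162001
female,84,0.09040488290885207
female,85,0.09989708001923892
female,86,0.11032409477739635
female,87,0.12176396307065007
female,88,0.1342979994085992
female,89,0.1480101109499653
female,90,0.16298585893182538
female,91,0.1793112202092254
female,92,0.19707099837635622
female,93,0.21634683248500086
female,94,0.23721475269660564
female,95,0.2597422375737024
female,96,0.28398473870396956
female,97,0.3099816568108913
female,98,0.33775178151718777
female,99,0.36728824665196746
female,100,1.0
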