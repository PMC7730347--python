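freq_hz,magnitude_db
0.05,-63.508016
0.05117057010527266,-62.697025
0.05236854489797248,-61.885735
0.05359456596025637,-61.074133
0.054849289894619166,-60.262208
0.05613338867554067,-59.44995
0.05744755000936545,-58.637345
0.05879247770260784,-57.824383
0.06016889203887946,-57.011051
0.06157753016464127,-56.197337
0.06301914648398636,-55.383228
0.06449451306266543,-54.568713
0.0660044200415709,-53.753779
0.06754967605990131,-52.938416
0.06913110868823277,-52.12261
0.07074956487172879,-51.306351
0.07240591138372668,-50.489627
0.07410103528994291,-49.67243
0.07583584442354611,-48.854748
0.07761126787135235,-48.036574
0.07942825647140263,-47.217899
0.0812877833221897,-46.398719
0.08319084430380644,-45.579026
0.08513845861129496,-44.758819
0.08713166930048248,-43.938097
0.08917154384659545,-43.116861
0.09125917471595216,-42.295115
0.09339567995103913,-41.472865
0.09558220376928507,-40.650124
0.09781991717585317,-39.826906
0.10011001859077921,-39.003231
0.10245373449079234,-38.179123
0.10485232006616163,-37.354614
0.10730705989292019,-36.529741
0.10981926862082728,-35.70455
0.11239029167743625,-34.879095
0.11502150598864588,-34.05344
0.11771432071612087,-33.227659
0.12047017801197624,-32.401839
0.12329055379113014,-31.57608
0.12617695852173827,-30.750497
0.12913093803413378,-29.925223
0.13215407434870527,-29.100408
0.13524798652315673,-28.276221
0.13841433151960328,-27.452858
0.14165480509196618,-26.630535
0.14497114269414382,-25.809499
0.14836512040944347,-24.990023
0.1518385559017729,-24.172415
0.15539330938910065,-23.357017
0.15903128463970592,-22.544208
0.16275442999175288,-21.73441
0.16656473939673366,-20.928086
0.17046425348734057,-20.125746
0.1744550606703386,-19.327948
0.17853929824502315,-18.535303
0.18271915354786278,-17.748474
0.18699686512393987,-16.968178
0.1913747239258156,-16.195188
0.19585507454046294,-15.430336
0.20044031644492324,-14.674505
0.20513290529135958,-13.928635
0.20993535422219547,-13.193719
0.214850235216042,-12.470794
0.21988018046513597,-11.760943
0.2250278837850249,-11.065283
0.23029610205725526,-10.38496
0.23568765670583616,-9.721136
0.24120543520826845,-9.07498
0.24685239264195008,-8.447654
0.252631553266784,-7.840297
0.25854601214483786,-7.254011
0.26459893679792207,-6.689842
0.27079356890397355,-6.14876
0.27713322603315527,-5.631646
0.2836213034245989,-5.139268
0.29026127580474487,-4.672264
0.2970566992482516,-4.231128
0.30401121308247114,-3.816193
0.31112854183651145,-3.42762
0.31841249723592935,-3.065392
0.32586698024412114,-2.729308
0.333495983151506,-2.418984
0.3413035917136194,-2.133861
0.3492939873392623,-1.873213
0.3574714493298789,-1.636165
0.36584035717135976,-1.421706
0.3744051928795011,-1.228716
0.3831705434003729,-1.055986
0.39214110306688393,-0.902242
0.40132167611285874,-0.766167
0.41071717924597123,-0.646428
0.4203326442809162,-0.541691
0.43017322083422516,-0.450641
0.44024417908217306,-0.372
0.450550912583251,-0.304538
0.4610989411667163,-0.24708
0.471893913888769,-0.198518
0.4829416120579351,-0.157815
0.4942479523312791,-0.124005
0.5058189898831035,-0.096197
0.517660921647831,-0.073575
0.5297800896388078,-0.055395
0.542182984344805,-0.040984
0.554876248206036,-0.029736
0.5678666791715525,-0.02111
0.5811612343399262,-0.014626
0.5947670336851597,-0.009864
0.6086913638698306,-0.006457
0.622941682147504,-0.004091
0.6375256203565066,-0.0025
0.652450989007201,-0.001465
0.6677257814649493,-0.000812
0.6833581782310032,-0.000409
0.6993565513236192,-0.000166
0.7157294687617396,-3.3e-05
0.7324856991536427,0.0
0.7496342163930226,-9.7e-05
0.7671842044650061,-0.000395
0.7851450623646886,-0.001003
0.8035264091308195,-0.002077
0.8223380889973316,-0.00381
0.8415901766654782,-0.006447
0.8612929826993931,-0.010274
0.8814570590479739,-0.015632
0.9020932046960363,-0.022909
0.9232124714477716,-0.032552
0.9448261698456046,-0.045063
0.9669458752276154,-0.061001
0.9895834339267785,-0.080988
1.0127509696153336,-0.105708
1.0364608897976852,-0.135906
1.0607258924553147,-0.172388
1.085558972847252,-0.216021
1.1109734304697618,-0.267725
1.1369828761789642,-0.32847
1.163601239480204,-0.399269
1.1908427759880789,-0.481164
1.21872207506111,-0.575219
1.247254067615158,-0.6825
1.2764540341197588,-0.804065
1.3063376127816637,-0.940943
1.336920807919973,-1.094116
1.3682199985373351,-1.264504
1.4002519470918153,-1.452946
1.4330338084741256,-1.660185
1.4665831391950217,-1.886861
1.5009179067877942,-2.133497
1.5360564994308785,-2.400498
1.5720177357957499,-2.688151
1.6088208751253683,-2.99663
1.6464856275485755,-3.325998
1.6850321646359638,-3.676227
1.7244811302028786,-4.047201
1.7648536513653248,-4.438734
1.8061713498547158,-4.850584
1.8484563535975138,-5.282459
1.8917313085659642,-5.734037
1.9360193909062773,-6.204966
1.9813443193507387,-6.694875
2.0277303679204146,-7.203374
2.075202378925238,-7.730061
2.123785776268449,-8.274516
2.173506579062512,-8.836303
2.2243914155637925,-9.414968
2.276467537433475,-10.010032
2.3297628343323407,-10.620993
2.3843058488572346,-11.247323
2.440125791827215,-11.888465
2.4972525579275695,-12.543834
2.555716741720084,-13.212821
2.6155496540281313,-13.894789
2.676783338705362,-14.589085
2.7394505897969705,-15.295036
2.8035849691027286,-16.011963
2.8692208241511974,-16.739176
2.936393306594741,-17.47599
3.0051383910351905,-18.221724
3.07549289429025,-18.975709
3.1474944951109434,-19.737291
3.2211817543606864,-20.50584
3.2965941356667736,-21.280746
3.373772026555346,-22.061429
3.4527567600811633,-22.847338
3.533590636963745,-23.637952
3.616316948241768,-24.432783
3.700979998457822,-25.231376
3.7876251293859555,-26.033308
3.8762987443147296,-26.838187
3.9670483328987456,-27.645653
4.059922496592006,-28.455376
4.154970974676697,-29.267054
4.252244670901338,-30.080413
4.35179568074258,-30.895204
4.4536773193052195,-31.711202
4.557944149875411,-32.528206
4.664652013142343,-33.346033
4.77385805710403,-34.164521
4.885620767673248,-34.983526
5.0,-35.802918
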