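# material = Au
# provenance = Drude + two critical points, Etchegoin et al., J. Chem. Phys. 125, 164705 (2006)
# generated_by = scripts/build_material_tables.py
wavelength_nm,n,k
400.0,1.474901,1.956696
405.0,1.473611,1.963019
410.0,1.471867,1.967174
415.0,1.469184,1.969043
420.0,1.465043,1.968600
425.0,1.458916,1.965918
430.0,1.450272,1.961170
435.0,1.438607,1.954633
440.0,1.423452,1.946683
445.0,1.404401,1.937793
450.0,1.381122,1.928516
455.0,1.353377,1.919482
460.0,1.321038,1.911375
465.0,1.284099,1.904919
470.0,1.242684,1.900853
475.0,1.197062,1.899906
480.0,1.147642,1.902772
485.0,1.094974,1.910068
490.0,1.039739,1.922310
495.0,0.982720,1.939869
500.0,0.924772,1.962949
505.0,0.866772,1.991565
510.0,0.809565,2.025545
515.0,0.753920,2.064545
520.0,0.700480,2.108085
525.0,0.649743,2.155595
530.0,0.602054,2.206461
535.0,0.557612,2.260068
540.0,0.516490,2.315833
545.0,0.478662,2.373226
550.0,0.444026,2.431785
555.0,0.412431,2.491114
560.0,0.383691,2.550885
565.0,0.357607,2.610831
570.0,0.333973,2.670738
575.0,0.312589,2.730438
580.0,0.293258,2.789801
585.0,0.275798,2.848729
590.0,0.260038,2.907150
595.0,0.245822,2.965013
600.0,0.233005,3.022283
605.0,0.221456,3.078938
610.0,0.211057,3.134967
615.0,0.201701,3.190368
620.0,0.193290,3.245142
625.0,0.185738,3.299298
630.0,0.178965,3.352848
635.0,0.172901,3.405805
640.0,0.167483,3.458185
645.0,0.162652,3.510005
650.0,0.158356,3.561284
655.0,0.154551,3.612040
660.0,0.151192,3.662292
665.0,0.148242,3.712057
670.0,0.145668,3.761354
675.0,0.143437,3.810202
680.0,0.141522,3.858618
685.0,0.139897,3.906618
690.0,0.138539,3.954220
695.0,0.137427,4.001439
700.0,0.136543,4.048291
705.0,0.135868,4.094789
710.0,0.135387,4.140950
715.0,0.135086,4.186785
720.0,0.134951,4.232307
725.0,0.134971,4.277530
730.0,0.135134,4.322465
735.0,0.135430,4.367123
740.0,0.135851,4.411515
745.0,0.136388,4.455652
750.0,0.137033,4.499542
755.0,0.137779,4.543196
760.0,0.138619,4.586622
765.0,0.139548,4.629829
770.0,0.140560,4.672825
775.0,0.141650,4.715617
780.0,0.142813,4.758214
785.0,0.144045,4.800622
790.0,0.145341,4.842848
795.0,0.146699,4.884898
800.0,0.148115,4.926779
805.0,0.149585,4.968496
810.0,0.151107,5.010055
815.0,0.152678,5.051461
820.0,0.154296,5.092720
825.0,0.155957,5.133836
830.0,0.157661,5.174814
835.0,0.159404,5.215659
840.0,0.161185,5.256374
845.0,0.163003,5.296965
850.0,0.164855,5.337434
855.0,0.166741,5.377786
860.0,0.168658,5.418024
865.0,0.170606,5.458152
870.0,0.172583,5.498173
875.0,0.174588,5.538090
880.0,0.176620,5.577907
885.0,0.178678,5.617626
890.0,0.180761,5.657251
895.0,0.182868,5.696783
900.0,0.184999,5.736225
905.0,0.187152,5.775581
910.0,0.189328,5.814852
915.0,0.191524,5.854041
920.0,0.193741,5.893150
925.0,0.195978,5.932181
930.0,0.198235,5.971136
935.0,0.200510,6.010017
940.0,0.202805,6.048827
945.0,0.205117,6.087567
950.0,0.207446,6.126238
955.0,0.209793,6.164843
960.0,0.212157,6.203384
965.0,0.214537,6.241861
970.0,0.216934,6.280276
975.0,0.219346,6.318632
980.0,0.221774,6.356928
985.0,0.224217,6.395168
990.0,0.226675,6.433352
995.0,0.229148,6.471481
1000.0,0.231636,6.509557
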