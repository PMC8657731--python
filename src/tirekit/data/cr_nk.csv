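# material = Cr
# provenance = Lorentz-Drude model, Rakic et al., Appl. Opt. 37, 5271 (1998)
# generated_by = scripts/build_material_tables.py
wavelength_nm,n,k
400.0,1.763401,3.557718
405.0,1.800758,3.591967
410.0,1.838345,3.625372
415.0,1.876142,3.657933
420.0,1.914128,3.689651
425.0,1.952282,3.720526
430.0,1.990584,3.750561
435.0,2.029012,3.779758
440.0,2.067546,3.808117
445.0,2.106164,3.835642
450.0,2.144845,3.862335
455.0,2.183569,3.888201
460.0,2.222315,3.913243
465.0,2.261061,3.937466
470.0,2.299787,3.960875
475.0,2.338472,3.983475
480.0,2.377096,4.005274
485.0,2.415639,4.026278
490.0,2.454082,4.046494
495.0,2.492403,4.065930
500.0,2.530585,4.084596
505.0,2.568608,4.102500
510.0,2.606453,4.119652
515.0,2.644103,4.136063
520.0,2.681539,4.151743
525.0,2.718744,4.166703
530.0,2.755702,4.180956
535.0,2.792397,4.194513
540.0,2.828812,4.207388
545.0,2.864932,4.219594
550.0,2.900742,4.231144
555.0,2.936230,4.242053
560.0,2.971380,4.252333
565.0,3.006180,4.262001
570.0,3.040619,4.271071
575.0,3.074684,4.279558
580.0,3.108364,4.287478
585.0,3.141649,4.294845
590.0,3.174530,4.301676
595.0,3.206996,4.307987
600.0,3.239041,4.313793
605.0,3.270655,4.319111
610.0,3.301832,4.323956
615.0,3.332566,4.328345
620.0,3.362849,4.332293
625.0,3.392678,4.335817
630.0,3.422046,4.338933
635.0,3.450951,4.341656
640.0,3.479387,4.344002
645.0,3.507353,4.345987
650.0,3.534846,4.347627
655.0,3.561863,4.348936
660.0,3.588404,4.349930
665.0,3.614467,4.350624
670.0,3.640051,4.351032
675.0,3.665157,4.351170
680.0,3.689784,4.351050
685.0,3.713934,4.350688
690.0,3.737608,4.350096
695.0,3.760807,4.349289
700.0,3.783533,4.348280
705.0,3.805788,4.347081
710.0,3.827576,4.345704
715.0,3.848898,4.344163
720.0,3.869758,4.342470
725.0,3.890159,4.340635
730.0,3.910105,4.338670
735.0,3.929600,4.336586
740.0,3.948648,4.334394
745.0,3.967253,4.332104
750.0,3.985420,4.329727
755.0,4.003153,4.327272
760.0,4.020458,4.324748
765.0,4.037339,4.322165
770.0,4.053801,4.319532
775.0,4.069850,4.316856
780.0,4.085491,4.314147
785.0,4.100730,4.311413
790.0,4.115571,4.308660
795.0,4.130021,4.305896
800.0,4.144084,4.303129
805.0,4.157768,4.300365
810.0,4.171077,4.297610
815.0,4.184018,4.294872
820.0,4.196595,4.292156
825.0,4.208816,4.289467
830.0,4.220685,4.286812
835.0,4.232209,4.284196
840.0,4.243393,4.281623
845.0,4.254243,4.279098
850.0,4.264766,4.276627
855.0,4.274965,4.274213
860.0,4.284849,4.271861
865.0,4.294421,4.269575
870.0,4.303688,4.267358
875.0,4.312655,4.265214
880.0,4.321329,4.263147
885.0,4.329714,4.261159
890.0,4.337815,4.259255
895.0,4.345639,4.257436
900.0,4.353191,4.255705
905.0,4.360476,4.254065
910.0,4.367499,4.252519
915.0,4.374265,4.251069
920.0,4.380780,4.249716
925.0,4.387049,4.248464
930.0,4.393076,4.247313
935.0,4.398866,4.246265
940.0,4.404425,4.245323
945.0,4.409757,4.244488
950.0,4.414867,4.243761
955.0,4.419759,4.243143
960.0,4.424438,4.242637
965.0,4.428909,4.242241
970.0,4.433175,4.241959
975.0,4.437242,4.241791
980.0,4.441113,4.241737
985.0,4.444793,4.241798
990.0,4.448286,4.241976
995.0,4.451595,4.242270
1000.0,4.454726,4.242682
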