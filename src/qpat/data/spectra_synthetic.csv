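# Synthetic fixture absorption spectra (not digitized measurements).
# alpha_CuSO4, alpha_NiSO4 in mm^-1 M^-1; alpha_water in mm^-1 per unit volume fraction.
wavelength_nm,alpha_CuSO4,alpha_NiSO4,alpha_water
680,0.405290,0.403265,0.0004307
685,0.435995,0.436473,0.0004673
690,0.468662,0.469513,0.0005080
695,0.503360,0.501833,0.0005524
700,0.540155,0.532856,0.0006000
705,0.579101,0.561994,0.0006958
710,0.620247,0.588665,0.0008709
715,0.663628,0.612316,0.0011042
720,0.709269,0.632436,0.0013747
725,0.757180,0.648582,0.0016614
730,0.807357,0.660388,0.0019432
735,0.859777,0.667583,0.0021989
740,0.914401,0.670000,0.0024077
745,0.971168,0.667583,0.0025484
750,1.029998,0.660388,0.0026000
755,1.090792,0.648582,0.0025832
760,1.153428,0.632436,0.0025376
765,1.217764,0.612316,0.0024704
770,1.283638,0.588665,0.0023888
775,1.350870,0.561994,0.0023000
780,1.419261,0.532856,0.0022112
785,1.488600,0.501833,0.0021296
790,1.558660,0.469513,0.0020624
795,1.629208,0.436473,0.0020168
800,1.700000,0.403265,0.0020000
805,1.770792,0.370398,0.0020428
810,1.841340,0.338327,0.0021625
815,1.911400,0.307447,0.0023459
820,1.980739,0.278085,0.0025796
825,2.049130,0.250500,0.0028505
830,2.116362,0.224879,0.0031454
835,2.182236,0.201345,0.0034510
840,2.246572,0.179959,0.0037541
845,2.309208,0.160727,0.0040415
850,2.370002,0.143606,0.0043000
855,2.428832,0.128517,0.0045224
860,2.485599,0.115348,0.0047185
865,2.540223,0.103964,0.0049006
870,2.592643,0.094216,0.0050806
875,2.642820,0.085948,0.0052708
880,2.690731,0.078998,0.0054834
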