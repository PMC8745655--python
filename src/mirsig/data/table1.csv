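accession,mirna,fold_A2780CR1,padj_A2780CR1,fold_A2780CR2,padj_A2780CR2,fold_A2780PR1,padj_A2780PR1,fold_A2780PR2,padj_A2780PR2
MIMAT0000073,hsa-miR-19a-3p,-1.65917506,0.43228235,-1.98693607,0.35808508,-2.98536661,0.03505245,-10.4632712,5.01e-5
MIMAT0000253,hsa-miR-10a-5p,1.11097524,0.92323367,1.16320532,0.93585887,-42.4402572,3.27e-7,-1.08606811,0.97947299
MIMAT0000254,hsa-miR-10b-5p,-1.45872281,0.55603288,1.15064247,0.93234778,-31.3998589,6.48e-8,1.05296136,0.98398973
MIMAT0004556,hsa-miR-10b-3p,-1.29212503,0.67767455,-2.01786429,0.21974679,-39.3922097,5.00e-9,-1.70229117,0.44748
MIMAT0000423,hsa-miR-125b-5p,11.4211844,2.92e-5,40.6263024,6.08e-8,1.20307908,0.81589843,11.7824642,2.23e-5
MIMAT0004603,hsa-miR-125b-2-3p,4.51279562,0.00034004,12.4460487,6.7e-7,1.10312933,0.88418483,-1.65376194,0.46375643
MIMAT0003233,hsa-miR-551b-3p,-10.2371817,0.00016236,-2.42299533,0.26166015,-8.30014759,0.00035114,-43.0163879,3.37e-7
MIMAT0004794,hsa-miR-551b-5p,-4.08033818,0.00021598,1.02804528,0.98248749,-8.7655429,9.75e-7,-14.4305295,7.61e-8
MIMAT0000097,hsa-miR-99a-5p,6.51698573,0.0002292,15.9710369,1.99e-6,-1.64710083,0.3694977,-6.10435252,0.00058133
MIMAT0000098,hsa-miR-100-5p,3.59432852,0.0002292,7.54674629,7.84e-7,-1.81342348,0.08262989,27.0328457,4.86e-10
MIMAT0000255,hsa-miR-34a-5p,-1.37990069,0.69602546,2.64309288,0.19626401,17.6185741,7.54e-6,-1.28683148,0.88713934
MIMAT0000266,hsa-miR-205-5p,1.14870533,0.82352945,1.28436927,0.77623732,541.061402,5.72e-14,1.16823451,0.90550058
MIMAT0000269,hsa-miR-212-3p,-10.7291338,1.38e-7,-3.28929656,0.00114186,-4.37436267,4.22e-5,-1.65503374,0.29893193
MIMAT0000275,hsa-miR-218-5p,-17.621278,2.9e-11,-19.7140856,1.1e-11,-23.6716147,2.01e-12,-20.6489829,1.04e-11
MIMAT0000278,hsa-miR-221-3p,-29.1177907,3.61e-9,-6.46450917,1.91e-5,7.0380716,7.54e-6,5.93519303,3.51e-5
MIMAT0000279,hsa-miR-222-3p,-25.6406319,1.77e-9,-7.69102525,1.18e-6,10.8507703,1.22e-7,6.98808889,2.74e-6
MIMAT0000435,hsa-miR-143-3p,1.10184923,0.92330223,3.61736322,0.04419363,51.5911963,5.58e-8,-2.05065576,0.39919454
MIMAT0000437,hsa-miR-145-5p,1.56380456,0.5547751,5.19999848,0.00954999,33.1841961,5.35e-7,1.13346619,0.9609715
MIMAT0000446,hsa-miR-127-3p,1.27885145,0.72151884,22.0754848,2.01e-7,6.77019849,0.00010088,-1.0050234,0.99757829
MIMAT0000447,hsa-miR-134-5p,1.73066708,0.35462069,19.4393236,8.85e-7,4.30931787,0.00288523,1.04986309,0.9857338
MIMAT0000617,hsa-miR-200c-3p,2.89984641,0.04105261,2.79275829,0.11093757,43.7996754,5.58e-8,1.42295677,0.78103834
MIMAT0000722,hsa-miR-370-3p,1.1993129,0.73879999,10.0811135,3.68e-7,3.63111596,0.00043284,-1.05947357,0.97809363
MIMAT0000733,hsa-miR-379-5p,1.3156419,0.64154083,35.5350551,6.58e-9,9.29366996,5.39e-6,-1.01200703,0.99713672
MIMAT0000737,hsa-miR-382-5p,1.18956511,0.78650898,13.2070959,4.72e-7,2.61591808,0.01777415,-1.15613669,0.917713
MIMAT0000738,hsa-miR-383-5p,1.61130832,0.51993375,3.39502246,0.07962031,-23.308018,2.64e-6,3.7157868,0.04800945
MIMAT0001639,hsa-miR-409-3p,1.15628694,0.8803879,37.5070461,2.25e-7,3.45870003,0.02255914,-1.07869628,0.97947299
MIMAT0002814,hsa-miR-432-5p,1.10745275,0.90787634,30.3020757,8.97e-8,2.98721279,0.02300484,-1.00458053,0.99757829
MIMAT0002816,hsa-miR-494-3p,2.21477167,0.08016448,15.7339127,4.72e-7,6.3051465,7.86e-5,1.04777446,0.98403533
MIMAT0003161,hsa-miR-493-3p,1.40219291,0.56211501,13.7967448,9.3e-7,3.73354575,0.00254391,1.02393083,0.99330976
MIMAT0003180,hsa-miR-487b-3p,-1.11202038,0.89278332,24.6411571,6.08e-8,4.91920683,0.00041598,-1.11767275,0.95525848
MIMAT0004679,hsa-miR-296-3p,25.7602551,3.61e-9,26.0457953,3.68e-9,5.52181059,2.73e-5,-1.72053781,0.32752008
MIMAT0004951,hsa-miR-887-3p,8.39589708,4.6e-5,11.275164,7.4e-6,1.00761536,0.99337741,30.7206627,7.61e-8
MIMAT0015052,hsa-miR-3175,19.7942794,0.04723357,14.0706299,0.17649319,2.31852234,0.67723594,3.4737797,0.6900128
MIMAT0015079,hsa-miR-3195,10.4085367,2.4e-8,2.47389546,0.00689315,9.66553716,3.15e-8,3.82713961,5.01e-5
MIMAT0018085,hsa-miR-3663-3p,5.92541055,0.00078701,1.63225249,0.60726441,15.958959,5.39e-6,1.73712026,0.57629842
MIMAT0018198,hsa-miR-3923,1.06673682,0.81082019,17.4769566,6.59e-13,-1.37200803,0.06414619,-1.16479559,0.64994842
MIMAT0018929,hsa-miR-4417,11.8440191,0.02326632,1.30060439,0.94186674,1.86127822,0.67559363,3.59369405,0.49679601
MIMAT0018968,hsa-miR-4449,11.5059173,0.00042964,4.67501587,0.05941838,14.4465126,0.00016476,3.43350257,0.16510969
MIMAT0019019,hsa-miR-4485,7.6322304,0.06607829,1.84506285,0.81936494,13.5381777,0.0140913,9.45065718,0.08956618
MIMAT0019071,hsa-miR-4532,10.4128366,7.15e-5,1.90699341,0.43120819,5.25328845,0.00186925,1.69206066,0.61415103
MIMAT0019835,hsa-miR-4721,10.42426,0.00841055,4.74531569,0.19626401,4.16202262,0.13162343,1.64195812,0.84365422
MIMAT0023693,hsa-miR-6068,9.29895604,0.00222206,1.55260856,0.80558365,10.1836996,0.00152316,-1.45736725,0.85496978
MIMAT0023700,hsa-miR-6075,9.5994209,1.68e-5,2.53750857,0.092133,10.6369796,5.11e-6,1.34386032,0.78827722
MIMAT0023705,hsa-miR-6080,10.7480047,0.00022974,2.04085944,0.46555248,7.78354196,0.00098186,-1.24777312,0.91729339
MIMAT0028121,hsa-miR-7112-5p,12.603672,6.0e-5,2.60552327,0.21041134,7.69985587,0.00042421,1.71625463,0.63266738
MIMAT0030991,hsa-miR-8064,4.40065316,0.00053009,1.05752722,0.96575158,14.2050075,4.10e-7,-1.18934073,0.90308138
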