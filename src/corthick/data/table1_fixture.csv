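subject_id,age,sex,source,caudal_anterior_cingulate_left,caudal_anterior_cingulate_right,caudal_middle_frontal_left,caudal_middle_frontal_right,cuneus_left,cuneus_right,entorhinal_left,entorhinal_right,fusiform_left,fusiform_right,inferior_parietal_left,inferior_parietal_right,inferior_temporal_left,inferior_temporal_right,isthmus_cingulate_left,isthmus_cingulate_right,lateral_occipital_left,lateral_occipital_right,lateral_orbitofrontal_left,lateral_orbitofrontal_right,lingual_left,lingual_right,medial_orbitofrontal_left,medial_orbitofrontal_right,middle_temporal_left,middle_temporal_right,parahippocampal_left,parahippocampal_right,paracentral_left,paracentral_right,pars_opercularis_left,pars_opercularis_right,pars_orbitalis_left,pars_orbitalis_right,pars_triangularis_left,pars_triangularis_right,pericalcarine_left,pericalcarine_right,postcentral_left,postcentral_right,posterior_cingulate_left,posterior_cingulate_right,precentral_left,precentral_right,precuneus_left,precuneus_right,rostral_anterior_cingulate_left,rostral_anterior_cingulate_right,rostral_middle_frontal_left,rostral_middle_frontal_right,superior_frontal_left,superior_frontal_right,superior_parietal_left,superior_parietal_right,superior_temporal_left,superior_temporal_right,supramarginal_left,supramarginal_right,transverse_temporal_left,transverse_temporal_right,insula_left,insula_right
ixi_1,39,U,IXI,2.432,2.395,2.23,2.326,1.895,1.663,3.356,3.728,2.486,2.558,2.426,2.356,2.892,2.751,2.214,2.086,2.017,2.097,2.522,2.795,1.774,1.762,2.53,2.444,2.856,2.825,2.456,2.509,2.108,2,2.665,2.307,2.464,2.529,2.243,2.4,1.441,1.308,1.98,1.901,2.397,2.311,2.28,2.339,2.28,2.231,2.69,2.899,2.224,2.34,2.558,2.565,2.135,1.978,2.774,2.826,2.482,2.414,1.893,1.968,3.072,2.749
mmrr_1,25,U,MMRR,2.981,3.201,2.634,2.578,1.918,1.761,4.093,3.868,2.657,2.67,2.307,2.303,2.777,2.832,2.702,2.38,1.863,1.962,3.085,2.95,2.096,2.086,2.701,2.628,2.792,2.845,3.339,3.143,2.579,2.395,2.69,2.768,2.893,2.771,2.533,2.431,1.528,1.642,2.349,2.262,2.79,2.655,2.248,2.344,2.625,2.438,3.118,3.406,2.383,2.356,2.674,2.812,2.198,2.084,2.824,3.023,2.577,2.577,2.713,2.628,3.169,3.242
nki_1,41,U,NKI,2.344,2.545,2.516,2.422,1.935,1.874,2.808,2.958,2.457,2.538,2.338,2.413,2.509,2.519,2.222,2.356,2.005,2.066,2.679,2.497,1.961,1.911,2.633,2.414,2.607,2.716,2.787,2.608,2.209,2.253,2.549,2.635,2.45,2.332,2.287,2.364,1.58,1.554,2.144,2.127,2.282,2.229,2.574,2.449,2.309,2.22,2.894,2.531,2.373,2.266,2.518,2.483,2.311,2.201,2.771,2.774,2.545,2.478,2.332,2.364,3.01,2.915
oasis_1,74,U,OASIS,2.7,2.694,2.351,2.413,1.682,1.805,2.876,3.053,2.274,2.199,2.221,2.267,2.57,2.205,2.031,2.35,2.085,2.001,2.538,2.604,1.784,1.837,2.159,2.553,2.561,2.548,2.035,2.496,2.214,2.136,2.456,2.528,2.308,2.612,2.077,2.243,1.482,1.454,2.094,2.039,2.234,2.432,2.317,2.231,2.285,2.126,3.041,2.908,2.283,2.15,2.592,2.477,2.128,2.168,2.614,2.633,2.302,2.309,2.621,2.285,2.942,3.049
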