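control_id,subpool,base_abundance,antisense,non_srm,reassigned_subpool
ERCC-00073,omitted,0,False,False,
ERCC-00162,A,1,False,False,
ERCC-00154,A,2,False,False,
ERCC-00144,A,4,False,False,
ERCC-00136,A,8,False,False,
ERCC-00126,A,16,False,False,
ERCC-00108,A,32,True,False,
ERCC-00096,A,64,False,False,
ERCC-00053,A,128,False,False,
ERCC-00077,A,256,False,False,
ERCC-00071,A,512,False,False,
ERCC-00060,A,1024,False,False,
ERCC-00084,A,2048,False,False,
ERCC-00043,A,4096,False,False,
ERCC-00035,A,8192,False,False,
ERCC-00025,A,16384,False,False,
ERCC-00079,A,32768,False,False,
ERCC-00170,A,65536,False,False,
ERCC-00114,A,131072,False,True,
ERCC-00003,A,262144,False,False,
ERCC-00012,A,1048576,False,False,
ERCC-00163,B,1,False,False,
ERCC-00156,B,2,False,False,
ERCC-00145,B,4,False,False,
ERCC-00137,B,8,False,False,
ERCC-00128,B,16,False,False,
ERCC-00116,B,32,True,False,
ERCC-00109,B,64,False,False,
ERCC-00097,B,128,False,False,
ERCC-00085,B,256,False,False,
ERCC-00078,B,512,False,False,
ERCC-00171,B,1024,False,False,
ERCC-00054,B,2048,False,False,
ERCC-00044,B,4096,False,False,
ERCC-00039,B,8192,False,False,
ERCC-00028,B,16384,False,False,
ERCC-00019,B,32768,False,False,
ERCC-00061,B,65536,False,False,
ERCC-00013,B,262144,False,False,
ERCC-00002,B,1048576,False,False,
ERCC-00164,C,1,False,False,
ERCC-00157,C,2,False,False,
ERCC-00147,C,4,False,False,
ERCC-00138,C,8,False,False,
ERCC-00130,C,16,False,False,
ERCC-00117,C,32,False,False,
ERCC-00111,C,64,False,False,
ERCC-00098,C,128,False,False,
ERCC-00086,C,256,False,False,
ERCC-00004,C,512,False,False,
ERCC-00074,C,1024,False,False,
ERCC-00057,C,2048,True,False,
ERCC-00062,C,4096,False,False,
ERCC-00046,C,8192,False,False,
ERCC-00040,C,16384,False,False,
ERCC-00051,C,32768,False,False,
ERCC-00022,C,65536,False,False,
ERCC-00014,C,262144,True,False,
ERCC-00018,C,1048576,False,False,
ERCC-00165,D,1,False,False,
ERCC-00158,D,2,False,False,
ERCC-00148,D,4,False,False,
ERCC-00142,D,8,False,False,
ERCC-00131,D,16,False,False,
ERCC-00120,D,32,False,False,
ERCC-00099,D,64,True,False,
ERCC-00112,D,128,False,False,
ERCC-00092,D,256,False,False,
ERCC-00081,D,512,False,False,
ERCC-00075,D,1024,False,False,
ERCC-00058,D,2048,False,False,
ERCC-00067,D,4096,False,False,
ERCC-00048,D,8192,False,False,
ERCC-00041,D,16384,False,False,
ERCC-00033,D,32768,False,False,
ERCC-00007,D,65536,False,False,
ERCC-00023,D,262144,False,False,
ERCC-00016,D,1048576,False,False,
ERCC-00123,E,1,False,False,
ERCC-00160,E,2,False,False,
ERCC-00150,E,4,False,False,
ERCC-00143,E,8,False,False,
ERCC-00134,E,16,False,False,
ERCC-00113,E,32,False,False,C
ERCC-00168,E,64,False,False,
ERCC-00104,E,128,False,False,
ERCC-00095,E,256,False,False,
ERCC-00083,E,512,False,False,
ERCC-00076,E,1024,False,False,
ERCC-00069,E,2048,False,False,
ERCC-00059,E,4096,True,False,
ERCC-00031,E,8192,False,False,
ERCC-00042,E,16384,False,False,
ERCC-00034,E,32768,False,False,
ERCC-00009,E,65536,True,False,
ERCC-00017,E,262144,False,False,
ERCC-00024,E,1048576,False,False,
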