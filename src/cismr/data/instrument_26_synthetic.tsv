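rsid	chromosome	base_pair_location	effect_allele	other_allele	effect_allele_frequency	beta	standard_error	p_value	n
var0000	1	154102271	A	G	0.26356858448594045	0.024211418649037298	0.0021156200103636252	2.516321392910138e-30	575531
var0001	1	154126873	C	T	0.09728942877594075	0.01953543377745947	0.0031451658443791674	5.256238187394256e-10	575531
var0002	1	154151475	G	A	0.17969599846716638	0.022558902745836874	0.002427694438744542	1.5096761636579732e-20	575531
var0003	1	154176077	T	C	0.15824702470597354	0.05796138432873495	0.002553821476457616	4.9130625868049795e-114	575531
var0004	1	154200679	A	G	0.370431168249318	0.030426132548798748	0.0019300798262873902	5.48769532959064e-56	575531
var0005	1	154225281	C	T	0.2903812090067121	0.011621611952590191	0.0020533067432351644	1.5141776977514544e-08	575531
var0006	1	154249883	G	A	0.1073098334089507	0.03432159926765939	0.003011483623795029	4.332379932317985e-30	575531
var0007	1	154274485	T	C	0.46398212358018937	0.032746316165616476	0.0018690046442499577	9.95489137252785e-69	575531
var0008	1	154299088	A	G	0.1112615272130744	0.053121493248223565	0.0029640883383496987	7.98544866676721e-72	575531
var0009	1	154323690	C	T	0.483436559391951	0.010480605034399314	0.0018651727566738672	1.9194711445621745e-08	575531
var0010	1	154348292	G	A	0.19532430843171145	0.04450110270300645	0.0023510510154361995	6.6839368812789765e-80	575531
var0011	1	154372894	T	C	0.45356732795797977	0.05863559122209134	0.001872239616625256	2.619512246460951e-215	575531
var0012	1	154397496	A	G	0.30936321258070976	0.012551075846990032	0.0020164685515611505	4.837556587964747e-10	575531
var0013	1	154422098	C	T	0.1889689533475969	0.04938842932810509	0.0023808754288351715	1.3942988146746467e-95	575531
var0014	1	154446700	G	A	0.3681633810970292	0.05117644354757878	0.0019325375915152912	1.584422541543048e-154	575531
var0015	1	154471302	T	C	0.3750525591424043	0.05630856857798902	0.001925230920061132	4.803671942353974e-188	575531
var0016	1	154495904	A	G	0.05231147247189311	0.036806446580047766	0.004186194064681988	1.4647512824327271e-18	575531
var0017	1	154520507	C	T	0.21770697920530901	0.042872314368811254	0.0022585501476590233	2.3923170256903657e-80	575531
var0018	1	154545109	G	A	0.07405223906785877	0.07088489846451773	0.0035594942967491243	3.057927668829771e-88	575531
var0019	1	154569711	T	C	0.14681501153769982	0.09174825108647809	0.0026335635762992373	6.456126509263956e-266	575531
var0020	1	154594313	A	G	0.07870395967461397	0.02711050318905128	0.0034614076403300183	4.793330861965004e-15	575531
var0021	1	154618915	C	T	0.06123703049391517	0.1543207087226902	0.00388745706239986	5e-324	575531
var0022	1	154643517	G	A	0.07668261592730566	0.1360573540378675	0.003502891418826118	5e-324	575531
var0023	1	154668119	T	C	0.4084030036891393	0.014316354139297166	0.0018962395379252385	4.357067813185359e-14	575531
var0024	1	154692721	A	G	0.1660107394754254	0.02280517552170044	0.0025049687970280163	8.708412211797815e-20	575531
var0025	1	154717323	C	T	0.3268633996354582	0.026327243827691468	0.001987082471621485	4.56066846523654e-40	575531
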