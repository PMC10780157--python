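index,abbreviation,full_name,group
1,S.C,Central sulcus,main
2,S.C.sylvian,Central sylvian sulcus,main
3,F.C.L,Lateral fissure (anterior and posterior parts),main
4,F.C.L.r.ant,Anterior ramus of the lateral fissure,main
5,F.C.L.r.asc,Ascending ramus of the lateral fissure,main
6,F.C.L.r.diag,Diagonal ramus of the lateral fissure,main
7,F.C.L.r.retroC.tr,Retro central transverse ramus of the lateral fissure,main
8,S.Pe.C.median,Median pre-central sulcus,main
9,S.Pe.C.marginal,Marginal pre-central sulcus,main
10,S.Pe.C.sup,Superior pre-central sulcus,main
11,S.Pe.C.inter,Intermediate pre-central sulcus,main
12,S.Pe.C.inf,Inferior pre-central sulcus,main
13,S.F.median,Median frontal sulcus,main
14,S.F.sup,Superior frontal sulcus,main
15,S.F.inter,Intermediate frontal sulcus,main
16,S.F.inf,Inferior frontal sulcus,main
17,S.F.inf.ant,Anterior inferior frontal sulcus,main
18,S.F.marginal,Marginal frontal sulcus,main
19,S.F.orbitaire,Orbital frontal sulcus,main
20,S.Or,Orbital sulcus,main
21,S.Po.C.sup,Superior post-central sulcus,main
22,S.GSM,Sulcus of the supramarginal gyrus,main
23,F.I.P,Intraparietal sulcus,main
24,F.I.P.Po.C.inf,Inferior post-central intraparietal sulcus,main
25,F.I.P.r.int.1,Primary intermediate ramus of the intraparietal sulcus,main
26,F.I.P.r.int.2,Secondary intermediate ramus of the intraparietal sulcus,main
27,S.O.p,Occipito polar sulcus,main
28,S.T.pol,Polar temporal sulcus,main
29,S.T.s,Superior temporal sulcus,main
30,S.T.s.ter.asc.ant,Anterior terminal ascending branch of the superior temporal sulcus,main
31,S.T.s.ter.asc.post,Posterior terminal ascending branch of the superior temporal sulcus,main
32,S.T.i.ant,Anterior inferior temporal sulcus,main
33,S.T.i.post,Posterior inferior temporal sulcus,main
34,F.C.M.post,Calloso-marginal posterior fissure,other
35,S.p.C,Paracentral sulcus,other
36,S.Pa.int,Internal parietal sulcus,other
37,F.P.O,Parieto-occipital fissure,other
38,S.Cu,Cuneal sulcus,other
39,S.Pa.sup,Superior parietal sulcus,other
40,S.Pa.t,Transverse parietal sulcus,other
41,S.O.T.lat.post,Posterior occipito-temporal lateral sulcus,other
42,Occipital,Occipital,other
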