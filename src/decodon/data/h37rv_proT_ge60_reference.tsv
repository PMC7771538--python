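Gene ID	Functional category	% proT
Rv0596c	Virulence, detoxification, adaptation	60
Rv1952	Virulence, detoxification, adaptation	60
Rv2865	Virulence, detoxification, adaptation	60
Rv2549c	Virulence, detoxification, adaptation	66.66666667
Rv1956	Virulence, detoxification, adaptation	71.42857143
Rv1982A	Virulence, detoxification, adaptation	75
Rv2863	Virulence, detoxification, adaptation	80
Rv0300	Virulence, detoxification, adaptation	100
Rv0550c	Virulence, detoxification, adaptation	100
Rv1103c	Virulence, detoxification, adaptation	100
Rv2760c	Virulence, detoxification, adaptation	100
Rv0737	Regulatory proteins	60
Rv3557c	Regulatory proteins	60
Rv3050c	Regulatory proteins	62.5
Rv1994c	Regulatory proteins	66.66666667
Rv0348	Regulatory proteins	71.42857143
Rv2021c	Regulatory proteins	100
Rv3653	PE/PPE	60
Rv0872c	PE/PPE	61.11111111
Rv2853	PE/PPE	61.11111111
Rv0354c	PE/PPE	62.5
Rv2162c	PE/PPE	62.5
Rv1068c	PE/PPE	63.63636364
Rv3512	PE/PPE	64.28571429
Rv0833	PE/PPE	64.70588235
Rv1441c	PE/PPE	64.70588235
Rv3367	PE/PPE	64.70588235
Rv1452c	PE/PPE	65.2173913
Rv1169c	PE/PPE	66.66666667
Rv1840c	PE/PPE	66.66666667
Rv0578c	PE/PPE	68.29268293
Rv0747	PE/PPE	68.42105263
Rv1468c	PE/PPE	80
Rv3508	PE/PPE	85.18518519
Rv3514	PE/PPE	90.32258065
Rv0470c	Lipid metabolism	60
Rv0972c	Lipid metabolism	60
Rv2724c	Lipid metabolism	60
Rv2982c	Lipid metabolism	60
Rv3221c	Lipid metabolism	100
Rv0771	Intermediary metabolism and respiration	60
Rv1851	Intermediary metabolism and respiration	60
Rv1826	Intermediary metabolism and respiration	60
Rv2499c	Intermediary metabolism and respiration	60
Rv2511	Intermediary metabolism and respiration	60
Rv2250A	Intermediary metabolism and respiration	63.63636364
Rv1692	Intermediary metabolism and respiration	64.70588235
Rv1311	Intermediary metabolism and respiration	66.66666667
Rv1555	Intermediary metabolism and respiration	66.66666667
Rv1990A	Intermediary metabolism and respiration	66.66666667
Rv2539c	Intermediary metabolism and respiration	66.66666667
Rv3145	Intermediary metabolism and respiration	66.66666667
Rv2421c	Intermediary metabolism and respiration	70
Rv3624c	Intermediary metabolism and respiration	70
Rv2754c	Intermediary metabolism and respiration	71.42857143
Rv0558	Intermediary metabolism and respiration	72.72727273
Rv0814c	Intermediary metabolism and respiration	75
Rv1305	Intermediary metabolism and respiration	75
Rv3118	Intermediary metabolism and respiration	75
Rv3154	Intermediary metabolism and respiration	77.77777778
Rv2537c	Intermediary metabolism and respiration	80
Rv0137c	Intermediary metabolism and respiration	81.81818182
Rv0763c	Intermediary metabolism and respiration	83.33333333
Rv0741	Insertion sequences and phages	60
Rv1586c	Insertion sequences and phages	60
Rv2014	Insertion sequences and phages	71.42857143
Rv3638	Insertion sequences and phages	71.42857143
Rv1702c	Insertion sequences and phages	74.19354839
Rv1584c	Insertion sequences and phages	75
Rv0094c	Insertion sequences and phages	77.27272727
Rv3467	Insertion sequences and phages	77.27272727
Rv1765A	Insertion sequences and phages	100
Rv1316c	Information pathways	60
Rv2069	Information pathways	60
Rv2906c	Information pathways	60
Rv2058c	Information pathways	66.66666667
Rv2056c	Information pathways	66.66666667
Rv1643	Information pathways	66.66666667
Rv0722	Information pathways	100
Rv2441c	Information pathways	100
Rv3053c	Information pathways	100
Rv3462c	Information pathways	100
Rv1772	Conserved hypotheticals	60
Rv0678	Conserved hypotheticals	60
Rv0607	Conserved hypotheticals	60
Rv3678A	Conserved hypotheticals	60
Rv1590	Conserved hypotheticals	60
Rv2283	Conserved hypotheticals	60
Rv2426c	Conserved hypotheticals	60
Rv2438A	Conserved hypotheticals	60
Rv2558	Conserved hypotheticals	60
Rv3224B	Conserved hypotheticals	60
Rv0323c	Conserved hypotheticals	63.63636364
Rv2257c	Conserved hypotheticals	64.70588235
Rv0078B	Conserved hypotheticals	66.66666667
Rv0181c	Conserved hypotheticals	66.66666667
Rv0530A	Conserved hypotheticals	66.66666667
Rv1120c	Conserved hypotheticals	66.66666667
Rv2820c	Conserved hypotheticals	66.66666667
Rv2239c	Conserved hypotheticals	66.66666667
Rv2342	Conserved hypotheticals	66.66666667
Rv2923c	Conserved hypotheticals	66.66666667
Rv3472	Conserved hypotheticals	66.66666667
Rv3033	Conserved hypotheticals	71.42857143
Rv0028	Conserved hypotheticals	75
Rv1890c	Conserved hypotheticals	75
Rv2603c	Conserved hypotheticals	75
Rv1066	Conserved hypotheticals	80
Rv2049c	Conserved hypotheticals	100
Rv0378	Conserved hypotheticals	100
Rv1893	Conserved hypotheticals	100
Rv1993c	Conserved hypotheticals	100
Rv2548A	Conserved hypotheticals	100
Rv2738c	Conserved hypotheticals	100
Rv3440c	Conserved hypotheticals	100
Rv0011c	Cell wall and cell processes	60
Rv0431	Cell wall and cell processes	60
Rv1463	Cell wall and cell processes	60
Rv1973	Cell wall and cell processes	60
Rv2856	Cell wall and cell processes	60
Rv2936	Cell wall and cell processes	61.53846154
Rv3864	Cell wall and cell processes	61.9047619
Rv3312A	Cell wall and cell processes	62.5
Rv0583c	Cell wall and cell processes	65
Rv2732c	Cell wall and cell processes	66.66666667
Rv3277	Cell wall and cell processes	66.66666667
Rv0476	Cell wall and cell processes	75
Rv1881c	Cell wall and cell processes	75
Rv2301	Cell wall and cell processes	75
Rv3271c	Cell wall and cell processes	75
Rv0900	Cell wall and cell processes	100
Rv0039c	Cell wall and cell processes	100
Rv0288	Cell wall and cell processes	100
Rv2520c	Cell wall and cell processes	100
Rv3789	Cell wall and cell processes	100
Rv3857c	Cell wall and cell processes	100
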