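Locus	Population	PIC	He	PE	PDF	PDM	MEC_df	MEC_t	MEC_d
DXS10074	Yugu	0.7565	0.7871	0.5754	0.9240	0.7871	0.5887	0.7565	0.6281
DXS10074	NMH	0.7482	0.7812	0.5646	0.9192	0.7812	0.5761	0.7482	0.6179
DXS10103	Yugu	0.7270	0.7633	0.5329	0.9077	0.7633	0.5487	0.7270	0.5927
DXS10103	NMH	0.7367	0.7713	0.5469	0.9131	0.7713	0.5607	0.7367	0.6039
DXS10135	Yugu	0.9023	0.9092	0.8143	0.9849	0.9092	0.8174	0.9023	0.8289
DXS10135	NMH	0.9072	0.9135	0.8232	0.9862	0.9135	0.8258	0.9070	0.8366
DXS7132	Yugu	0.6995	0.7395	0.4920	0.8921	0.7395	0.5138	0.6995	0.5603
DXS7132	NMH	0.7138	0.7536	0.5159	0.8995	0.7536	0.5292	0.7138	0.5768
DXS7423	Yugu	0.5241	0.5949	0.2848	0.7651	0.5949	0.3195	0.5167	0.3794
DXS7423	NMH	0.4433	0.5252	0.2105	0.6927	0.5252	0.2535	0.4433	0.3049
DXS8378	Yugu	0.5234	0.5945	0.2844	0.7645	0.5945	0.3252	0.5233	0.3786
DXS8378	NMH	0.5503	0.6127	0.3064	0.7876	0.6127	0.3510	0.5503	0.4032
HPRTB	Yugu	0.6753	0.7249	0.4678	0.8748	0.7249	0.4780	0.6753	0.5332
HPRTB	NMH	0.6633	0.7106	0.4448	0.8690	0.7106	0.4698	0.6633	0.5203
DXS10075	Yugu	0.6600	0.7064	0.4382	0.8675	0.7064	0.4675	0.6600	0.5167
DXS10075	NMH	0.6604	0.7062	0.4379	0.8678	0.7062	0.4707	0.6604	0.5178
DXS10079	Yugu	0.7718	0.7995	0.5982	0.9320	0.7995	0.6095	0.7718	0.6467
DXS10079	NMH	0.7745	0.8017	0.6022	0.9335	0.8017	0.6144	0.7745	0.6506
DXS101	Yugu	0.8004	0.8225	0.6414	0.9464	0.8225	0.6534	0.8004	0.6840
DXS101	NMH	0.7790	0.8058	0.6098	0.9355	0.8058	0.6205	0.7790	0.6563
DXS10148	Yugu	0.8914	0.8997	0.7948	0.9817	0.8997	0.7987	0.8914	0.8121
DXS10148	NMH	0.8978	0.9056	0.8069	0.9833	0.9056	0.8080	0.8978	0.8212
DXS10159	Yugu	0.7463	0.7801	0.5627	0.9179	0.7801	0.5721	0.7463	0.6153
DXS10159	NMH	0.7467	0.7807	0.5638	0.9179	0.7807	0.5728	0.7467	0.6160
DXS10162	Yugu	0.6790	0.7245	0.4672	0.8786	0.7245	0.4878	0.6790	0.5378
DXS10162	NMH	0.7351	0.7712	0.5467	0.9116	0.7712	0.5569	0.7351	0.6019
DXS10164	Yugu	0.5520	0.5908	0.2800	0.7937	0.5908	0.3690	0.5520	0.4031
DXS10164	NMH	0.5672	0.6066	0.2989	0.8059	0.6066	0.3845	0.5672	0.4189
DXS6789	Yugu	0.7563	0.7886	0.5780	0.9230	0.7886	0.5846	0.7563	0.6271
DXS6789	NMH	0.7934	0.8177	0.6323	0.9425	0.8177	0.6409	0.7934	0.6745
DXS6795	Yugu	0.6648	0.7065	0.4383	0.8722	0.7065	0.4772	0.6648	0.5218
DXS6795	NMH	0.6503	0.6946	0.4200	0.8624	0.6946	0.4627	0.6503	0.5069
DXS6800	Yugu	0.4430	0.4682	0.1612	0.6919	0.4682	0.2809	0.4430	0.3004
DXS6800	NMH	0.2913	0.3063	0.0662	0.5037	0.3063	0.1677	0.2913	0.1775
DXS6807	Yugu	0.5805	0.6462	0.3500	0.8091	0.6462	0.3805	0.5805	0.4353
DXS6807	NMH	0.6091	0.6698	0.3831	0.8303	0.6698	0.4093	0.6091	0.4642
DXS6809	Yugu	0.7990	0.8231	0.6426	0.9446	0.8231	0.6470	0.7990	0.6812
DXS6809	NMH	0.7859	0.8121	0.6216	0.9385	0.8121	0.6281	0.7859	0.6643
DXS6810	Yugu	0.5744	0.6412	0.3433	0.8044	0.6412	0.3675	0.5744	0.4273
DXS6810	NMH	0.5431	0.6167	0.3114	0.7795	0.6167	0.3352	0.5431	0.3966
DXS7133	Yugu	0.3995	0.4343	0.1362	0.6452	0.4343	0.2381	0.3995	0.2627
DXS7133	NMH	0.3957	0.4452	0.1439	0.6427	0.4452	0.2285	0.3957	0.2603
DXS981	Yugu	0.7786	0.8055	0.6093	0.9353	0.8055	0.6194	0.7786	0.6556
DXS981	NMH	0.8193	0.8383	0.6720	0.9549	0.8383	0.6811	0.8193	0.7087
DXS9902	Yugu	0.6140	0.6764	0.3927	0.8329	0.6764	0.4070	0.6140	0.4678
DXS9902	NMH	0.5838	0.6488	0.3535	0.8117	0.6488	0.3768	0.5838	0.4366
DXS9907	Yugu	0.5029	0.5850	0.2733	0.7456	0.5850	0.3034	0.5029	0.3605
DXS9907	NMH	0.5469	0.6197	0.3152	0.7826	0.6197	0.3480	0.5469	0.4028
GATA165B12	Yugu	0.5839	0.6367	0.3372	0.8153	0.6367	0.3857	0.5839	0.4355
GATA165B12	NMH	0.5332	0.5901	0.2792	0.7751	0.5901	0.3362	0.5332	0.3850
GATA172D05	Yugu	0.7235	0.7558	0.5198	0.9080	0.7558	0.5490	0.7235	0.5884
GATA172D05	NMH	0.6944	0.7331	0.4814	0.8901	0.7331	0.5108	0.6944	0.5549
GATA31E08	Yugu	0.7141	0.7539	0.5165	0.8996	0.7539	0.5305	0.7141	0.5776
GATA31E08	NMH	0.7314	0.7664	0.5383	0.9104	0.7664	0.5541	0.7314	0.5975
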