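	PC3	MCF7GhentB	ACHN	786-O	Normal1-singleton-B	OVCAR-5	MDA-MB-231	DU-145	IGROV-1	SN12C	Normal1-duplicate-A	HT-29	HCT116	MOLT-4	HCT-15	Normal2-singleton-B	CCRF-CEM	Normal1-singleton-A	BT-549	MCF7	Normal2-singleton-A	RPMI-8226	Normal1-duplicate-B
PC3	1.000	0.884	0.872	0.844	0.843	0.798	0.846	0.877	0.926	0.882	0.840	0.851	0.946	0.858	0.833	0.842	0.959	0.832	0.859	0.840	0.861	0.855	0.860
MCF7GhentB	0.884	1.000	0.910	0.864	0.901	0.799	0.861	0.909	0.905	0.901	0.945	0.888	0.911	0.904	0.852	0.883	0.907	0.897	0.887	0.878	0.908	0.876	0.951
ACHN	0.872	0.910	1.000	0.865	0.932	0.825	0.864	0.919	0.900	0.914	0.902	0.939	0.907	0.900	0.867	0.931	0.909	0.932	0.903	0.945	0.957	0.945	0.917
786-O	0.844	0.864	0.865	1.000	0.870	0.904	0.965	0.928	0.892	0.910	0.885	0.832	0.887	0.938	0.969	0.832	0.870	0.864	0.900	0.827	0.855	0.824	0.884
Normal1-singleton-B	0.843	0.901	0.932	0.870	1.000	0.804	0.861	0.920	0.887	0.902	0.915	0.924	0.880	0.919	0.858	0.915	0.876	0.950	0.894	0.918	0.944	0.912	0.918
OVCAR-5	0.798	0.799	0.825	0.904	0.804	1.000	0.936	0.887	0.798	0.928	0.794	0.812	0.816	0.853	0.927	0.836	0.817	0.805	0.933	0.857	0.826	0.838	0.829
MDA-MB-231	0.846	0.861	0.864	0.965	0.861	0.936	1.000	0.940	0.865	0.935	0.863	0.855	0.875	0.928	0.975	0.854	0.865	0.859	0.928	0.855	0.865	0.853	0.879
DU-145	0.877	0.909	0.919	0.928	0.920	0.887	0.940	1.000	0.910	0.953	0.916	0.890	0.911	0.965	0.938	0.903	0.907	0.908	0.950	0.896	0.923	0.893	0.931
IGROV-1	0.926	0.905	0.900	0.892	0.887	0.798	0.865	0.910	1.000	0.894	0.890	0.869	0.975	0.917	0.870	0.856	0.948	0.883	0.867	0.846	0.885	0.846	0.889
SN12C	0.882	0.901	0.914	0.910	0.902	0.928	0.935	0.953	0.894	1.000	0.886	0.896	0.906	0.933	0.919	0.906	0.902	0.901	0.963	0.919	0.913	0.899	0.914
Normal1-duplicate-A	0.840	0.945	0.902	0.885	0.915	0.794	0.863	0.916	0.890	0.886	1.000	0.868	0.881	0.933	0.868	0.869	0.868	0.910	0.881	0.863	0.901	0.858	0.973
HT-29	0.851	0.888	0.939	0.832	0.924	0.812	0.855	0.890	0.869	0.896	0.868	1.000	0.877	0.864	0.838	0.933	0.880	0.925	0.891	0.948	0.941	0.950	0.893
HCT116	0.946	0.911	0.907	0.887	0.880	0.816	0.875	0.911	0.975	0.906	0.881	0.877	1.000	0.910	0.872	0.867	0.960	0.879	0.883	0.865	0.892	0.870	0.890
MOLT-4	0.858	0.904	0.900	0.938	0.919	0.853	0.928	0.965	0.917	0.933	0.933	0.864	0.910	1.000	0.931	0.875	0.891	0.919	0.917	0.861	0.899	0.852	0.924
HCT-15	0.833	0.852	0.867	0.969	0.858	0.927	0.975	0.938	0.870	0.919	0.868	0.838	0.872	0.931	1.000	0.844	0.863	0.855	0.913	0.836	0.862	0.839	0.880
Normal2-singleton-B	0.842	0.883	0.931	0.832	0.915	0.836	0.854	0.903	0.856	0.906	0.869	0.933	0.867	0.875	0.844	1.000	0.881	0.913	0.912	0.942	0.946	0.945	0.900
CCRF-CEM	0.959	0.907	0.909	0.870	0.876	0.817	0.865	0.907	0.948	0.902	0.868	0.880	0.960	0.891	0.863	0.881	1.000	0.871	0.889	0.871	0.898	0.882	0.890
Normal1-singleton-A	0.832	0.897	0.932	0.864	0.950	0.805	0.859	0.908	0.883	0.901	0.910	0.925	0.879	0.919	0.855	0.913	0.871	1.000	0.889	0.922	0.936	0.910	0.914
BT-549	0.859	0.887	0.903	0.900	0.894	0.933	0.928	0.950	0.867	0.963	0.881	0.891	0.883	0.917	0.913	0.912	0.889	0.889	1.000	0.928	0.913	0.915	0.910
MCF7	0.840	0.878	0.945	0.827	0.918	0.857	0.855	0.896	0.846	0.919	0.863	0.948	0.865	0.861	0.836	0.942	0.871	0.922	0.928	1.000	0.946	0.966	0.897
Normal2-singleton-A	0.861	0.908	0.957	0.855	0.944	0.826	0.865	0.923	0.885	0.913	0.901	0.941	0.892	0.899	0.862	0.946	0.898	0.936	0.913	0.946	1.000	0.956	0.922
RPMI-8226	0.855	0.876	0.945	0.824	0.912	0.838	0.853	0.893	0.846	0.899	0.858	0.950	0.870	0.852	0.839	0.945	0.882	0.910	0.915	0.966	0.956	1.000	0.889
Normal1-duplicate-B	0.860	0.951	0.917	0.884	0.918	0.829	0.879	0.931	0.889	0.914	0.973	0.893	0.890	0.924	0.880	0.900	0.890	0.914	0.910	0.897	0.922	0.889	1.000
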