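# Universal single-copy marker set, 111 genes.
# Placeholder ids; replace with your preferred essential-gene catalog.
ESS_001
ESS_002
ESS_003
ESS_004
ESS_005
ESS_006
ESS_007
ESS_008
ESS_009
ESS_010
ESS_011
ESS_012
ESS_013
ESS_014
ESS_015
ESS_016
ESS_017
ESS_018
ESS_019
ESS_020
ESS_021
ESS_022
ESS_023
ESS_024
ESS_025
ESS_026
ESS_027
ESS_028
ESS_029
ESS_030
ESS_031
ESS_032
ESS_033
ESS_034
ESS_035
ESS_036
ESS_037
ESS_038
ESS_039
ESS_040
ESS_041
ESS_042
ESS_043
ESS_044
ESS_045
ESS_046
ESS_047
ESS_048
ESS_049
ESS_050
ESS_051
ESS_052
ESS_053
ESS_054
ESS_055
ESS_056
ESS_057
ESS_058
ESS_059
ESS_060
ESS_061
ESS_062
ESS_063
ESS_064
ESS_065
ESS_066
ESS_067
ESS_068
ESS_069
ESS_070
ESS_071
ESS_072
ESS_073
ESS_074
ESS_075
ESS_076
ESS_077
ESS_078
ESS_079
ESS_080
ESS_081
ESS_082
ESS_083
ESS_084
ESS_085
ESS_086
ESS_087
ESS_088
ESS_089
ESS_090
ESS_091
ESS_092
ESS_093
ESS_094
ESS_095
ESS_096
ESS_097
ESS_098
ESS_099
ESS_100
ESS_101
ESS_102
ESS_103
ESS_104
ESS_105
ESS_106
ESS_107
ESS_108
ESS_109
ESS_110
ESS_111
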