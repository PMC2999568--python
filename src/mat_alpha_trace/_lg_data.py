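"""Published Le-Gascuel (LG) amino-acid replacement model data.

Exchangeabilities are the 190 lower-triangular entries (column-major,
PAML residue order A R N D C Q E G H I L K M F P S T W Y V) of the
symmetric LG exchangeability matrix, with the accompanying stationary
amino-acid frequencies.
"""

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

# fmt: off
LG_EXCHANGEABILITIES_LOWER = [
    0.4250929999999999986, 0.2768180000000000085, 0.3951439999999999952, 2.4890840000000000742, 0.9698940000000000339,
    1.0385450000000000514, 2.0660400000000000986, 0.3588580000000000103, 0.1498299999999999910, 0.3953369999999999940,
    0.5365180000000000504, 1.1240349999999998953, 0.2537010000000000098, 1.1776510000000000034, 4.7271819999999999951,
    2.1395010000000000971, 0.1807169999999999888, 0.2189589999999999870, 2.5478700000000000792, 0.7518780000000000463,
    0.1239539999999999947, 0.5345509999999999984, 2.8079079999999998485, 0.3639700000000000157, 0.3901919999999999833,
    2.4266009999999997859, 0.1269909999999999928, 0.3018480000000000052, 6.3260670000000001068, 0.4841329999999999800,
    0.0527219999999999980, 0.3325330000000000230, 0.8581509999999999971, 0.5789870000000000294, 0.5936069999999999958,
    0.3144399999999999973, 0.1708870000000000111, 5.0761490000000000222, 0.5287680000000000158, 1.6957519999999999261,
    0.5417119999999999713, 1.4376450000000000617, 4.5092379999999998574, 0.1915030000000000066, 0.0684270000000000017,
    2.1450779999999998182, 0.3710040000000000004, 0.0895249999999999935, 0.1617869999999999864, 4.0083580000000003096,
    2.0006789999999998741, 0.0453759999999999997, 0.6120250000000000412, 0.0836879999999999985, 0.0625560000000000005,
    0.5233860000000000179, 5.2438700000000002532, 0.8449259999999999549, 0.9271139999999999937, 0.0106899999999999998,
    0.0150760000000000009, 0.2829590000000000161, 0.0255480000000000013, 0.0174160000000000009, 0.3944559999999999733,
    1.2402750000000000163, 0.4258600000000000163, 0.0298899999999999999, 0.1351070000000000049, 0.0379670000000000007,
    0.0848079999999999945, 0.0034989999999999999, 0.5692650000000000210, 0.6405429999999999735, 0.3206269999999999953,
    0.5940069999999999517, 0.0132660000000000000, 0.8936800000000000299, 1.1052509999999999835, 0.0753820000000000046,
    2.7844780000000000086, 1.1434800000000000519, 0.6701279999999999459, 1.1655320000000000125, 1.9592909999999998938,
    4.1285910000000001219, 0.2679590000000000027, 4.8135050000000001447, 0.0728540000000000021, 0.5824570000000000025,
    3.2342939999999997802, 1.6725689999999999724, 0.0358549999999999980, 0.6242940000000000156, 1.2238279999999999159,
    1.0801359999999999850, 0.2361989999999999923, 0.2573360000000000092, 0.2103319999999999912, 0.3488470000000000182,
    0.4238810000000000078, 0.0442649999999999988, 0.0696729999999999988, 1.8071770000000000334, 0.1737350000000000005,
    0.0188110000000000013, 0.4194089999999999763, 0.6119729999999999892, 0.6045449999999999990, 0.0778520000000000045,
    0.1200370000000000048, 0.2450340000000000018, 0.3114839999999999831, 0.0087049999999999992, 0.0442610000000000017,
    0.2966360000000000108, 0.1395379999999999954, 0.0895859999999999990, 0.1969609999999999972, 1.7399899999999999256,
    0.1298360000000000070, 0.2684909999999999797, 0.0546789999999999984, 0.0767010000000000053, 0.1088820000000000066,
    0.3663170000000000037, 0.6972639999999999949, 0.4424719999999999764, 0.6821390000000000509, 0.5088510000000000533,
    0.9900120000000000031, 0.5842619999999999481, 0.5970539999999999736, 5.3068340000000002732, 0.1190129999999999938,
    4.1450670000000000570, 0.1590689999999999882, 4.2736070000000001556, 1.1127270000000000216, 0.0782810000000000034,
    0.0641049999999999953, 1.0337389999999999635, 0.1116599999999999954, 0.2325230000000000075, 10.6491070000000007667,
    0.1375000000000000111, 6.3123579999999996915, 2.5926919999999999966, 0.2490600000000000036, 0.1822870000000000046,
    0.3029359999999999831, 0.6196319999999999606, 0.2996480000000000254, 1.7027449999999999530, 0.6566039999999999655,
    0.0239179999999999983, 0.3903220000000000023, 0.7486829999999999874, 1.1368629999999999569, 0.0499059999999999990,
    0.1319319999999999937, 0.1852020000000000055, 1.7988530000000000353, 0.0998489999999999933, 0.3469599999999999906,
    2.0203660000000001062, 0.6961749999999999883, 0.4813060000000000116, 1.8987179999999999058, 0.0944640000000000063,
    0.3618190000000000017, 0.1650010000000000088, 2.4571209999999998885, 7.8039019999999998944, 0.6546830000000000149,
    1.3381320000000000991, 0.5714679999999999760, 0.0951309999999999933, 0.0896129999999999982, 0.2965010000000000145,
    6.4722790000000003374, 0.2488619999999999999, 0.4005469999999999864, 0.0983689999999999981, 0.1408250000000000057,
    0.2458410000000000040, 2.1881580000000000474, 3.1518150000000000333, 0.1895100000000000118, 0.2493130000000000068,
]

LG_FREQUENCIES = [
    0.079065920934079076, 0.055940944059055940, 0.041976958023041980, 0.053051946948053055,
    0.012936987063012939, 0.040766959233040766, 0.071585928414071590, 0.057336942663057340,
    0.022354977645022357, 0.062156937843062157, 0.099080900919099088, 0.064599935400064604,
    0.022950977049022953, 0.042301957698042306, 0.044039955960044043, 0.061196938803061200,
    0.053286946713053292, 0.012065987934012068, 0.034154965845034156, 0.069146930853069152,
]
# fmt: on

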