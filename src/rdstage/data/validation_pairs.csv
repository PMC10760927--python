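case_id,stage_a,stage_b
V001,I,I
V002,I,I
V003,I,I
V004,I,I
V005,I,I
V006,I,I
V007,I,I
V008,I,I
V009,I,I
V010,I,I
V011,I,I
V012,I,I
V013,I,I
V014,I,I
V015,I,I
V016,I,II
V017,I,IV
V018,II,II
V019,II,II
V020,II,II
V021,II,II
V022,II,II
V023,II,II
V024,II,II
V025,II,II
V026,II,II
V027,II,II
V028,II,II
V029,II,II
V030,II,II
V031,II,II
V032,II,II
V033,II,II
V034,II,III
V035,II,III
V036,II,III
V037,II,III
V038,III,I
V039,III,I
V040,III,III
V041,III,III
V042,III,III
V043,III,III
V044,III,III
V045,III,III
V046,III,III
V047,III,III
V048,IV,I
V049,IV,I
V050,IV,III
V051,IV,IV
V052,IV,IV
V053,IV,IV
V054,IV,IV
V055,IV,IV
V056,IV,IV
V057,IV,IV
V058,IV,IV
V059,IV,IV
V060,IV,IV
V061,IV,IV
V062,IV,IV
V063,IV,IV
V064,IV,IV
V065,IV,IV
V066,IV,IV
V067,IV,IV
V068,IV,IV
V069,IV,IV
V070,IV,IV
V071,IV,IV
V072,IV,IV
V073,IV,IV
V074,IV,IV
V075,IV,IV
V076,IV,IV
V077,IV,IV
V078,IV,IV
V079,IV,IV
V080,IV,IV
V081,IV,IV
V082,IV,IV
V083,IV,IV
V084,IV,IV
V085,IV,IV
V086,IV,IV
V087,IV,IV
V088,IV,IV
V089,IV,IV
V090,IV,IV
V091,IV,IV
V092,IV,IV
V093,IV,IV
V094,IV,IV
V095,IV,IV
V096,IV,IV
V097,IV,IV
V098,IV,IV
V099,IV,IV
V100,IV,IV
V101,IV,IV
V102,IV,IV
V103,IV,IV
V104,IV,IV
V105,IV,IV
V106,IV,IV
V107,IV,IV
V108,IV,IV
V109,IV,IV
V110,IV,IV
V111,IV,IV
V112,IV,IV
V113,IV,IV
V114,IV,IV
V115,IV,IV
V116,IV,IV
V117,IV,IV
V118,IV,IV
V119,IV,IV
V120,IV,IV
V121,IV,IV
V122,IV,IV
V123,IV,IV
V124,IV,IV
V125,IV,IV
V126,IV,IV
V127,IV,IV
V128,IV,IV
V129,IV,IV
V130,IV,IV
V131,IV,IV
V132,IV,IV
V133,IV,IV
V134,IV,IV
V135,IV,IV
V136,IV,IV
V137,IV,IV
V138,IV,IV
V139,IV,IV
V140,IV,IV
V141,IV,IV
V142,IV,IV
V143,IV,IV
V144,IV,IV
V145,IV,IV
V146,IV,IV
V147,IV,IV
V148,IV,IV
V149,IV,IV
V150,IV,IV
V151,IV,IV
V152,IV,IV
V153,IV,IV
V154,IV,IV
V155,IV,IV
V156,IV,IV
V157,IV,IV
V158,IV,IV
V159,IV,IV
V160,IV,IV
V161,IV,IV
V162,IV,IV
V163,IV,IV
V164,IV,IV
V165,IV,IV
V166,IV,IV
V167,IV,IV
V168,IV,IV
V169,IV,IV
V170,IV,IV
V171,IV,IV
V172,IV,IV
V173,IV,IV
V174,IV,IV
V175,IV,IV
V176,IV,IV
V177,IV,IV
V178,IV,IV
V179,IV,IV
V180,IV,IV
V181,IV,IV
V182,IV,IV
V183,IV,IV
V184,IV,IV
V185,IV,IV
V186,IV,IV
V187,IV,IV
V188,IV,IV
V189,IV,IV
V190,IV,IV
V191,IV,IV
V192,IV,IV
V193,IV,IV
V194,IV,IV
V195,IV,IV
V196,IV,IV
V197,IV,IV
V198,IV,IV
V199,IV,IV
V200,IV,IV
V201,IV,IV
V202,IV,IV
V203,IV,IV
V204,IV,IV
V205,IV,IV
V206,IV,IV
V207,IV,IV
V208,IV,IV
V209,IV,IV
V210,IV,IV
V211,IV,IV
V212,IV,IV
V213,IV,IV
V214,IV,IV
V215,IV,IV
V216,IV,IV
V217,IV,IV
V218,IV,IV
V219,IV,IV
V220,IV,IV
V221,IV,IV
V222,IV,IV
V223,IV,IV
V224,IV,IV
V225,IV,IV
V226,IV,IV
V227,IV,IV
V228,IV,IV
V229,IV,IV
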