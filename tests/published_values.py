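"""Published APC-IE results used as cross-check inputs by the tests.

Coefficient columns (4 decimal places) and fit statistics from the
published three-country analysis of breast, cervical and ovarian
cancer mortality.  These are test inputs — the implementation never
reads them.  Only fully displayed columns are included: the long-series
Japan and Singapore breast/cervical fits are displayed on a common
window in the source tables, so their printed columns deliberately do
not sum to zero and are unusable as centering checks.
"""

# (deviance, A, P, published BIC) for all nine country x cancer fits.
PUBLISHED_FIT_STATS = {
    "japan_breast": (1.6419, 12, 12, -495.3394),
    "korea_breast": (0.6994, 12, 5, -122.1310),
    "singapore_breast": (29.1817, 12, 10, -353.8176),
    "japan_cervical": (1.7567, 12, 12, -495.2246),
    "korea_cervical": (1.1981, 12, 5, -121.6323),
    "singapore_cervical": (30.4706, 12, 10, -352.5287),
    "japan_ovarian": (0.0872, 12, 4, -77.3368),
    "korea_ovarian": (0.4661, 12, 4, -76.9580),
    "singapore_ovarian": (4.6688, 12, 4, -72.7553),
}

# Fully displayed effect columns: each must sum to 0 within print rounding.
PUBLISHED_FULL_COLUMNS = {
    "korea_breast_age": [
        -2.9416, -1.4373, -0.3749, 0.0834, 0.4238, 0.7089,
        0.7763, 0.7491, 0.6295, 0.4515, 0.4367, 0.4947,
    ],
    "korea_breast_period": [-0.4497, -0.1713, 0.0171, 0.2135, 0.3904],
    "korea_breast_cohort": [
        0.4849, 0.6056, 0.5468, 0.4849, 0.4425, 0.4783, 0.4758, 0.3094,
        0.2152, 0.1882, 0.0210, -0.0828, -0.2374, -0.8212, -0.9692, -2.1420,
    ],
    "korea_cervical_age": [
        -3.4937, -1.6183, -0.4979, 0.1162, 0.4420, 0.6746,
        0.6856, 0.6305, 0.6354, 0.6316, 0.7776, 1.0164,
    ],
    "korea_cervical_period": [-0.5241, -0.1242, 0.1925, 0.3089, 0.1470],
    "korea_cervical_cohort": [
        0.3426, 0.5863, 0.8657, 0.9048, 0.6902, 0.5823, 0.3043, -0.0015,
        -0.1655, -0.2699, -0.5451, -0.7526, -0.8588, -0.5983, -0.4424, -0.6419,
    ],
    "japan_ovarian_age": [
        -1.9564, -1.7304, -1.0773, -0.5521, 0.0071, 0.5464,
        0.8483, 0.8943, 0.8378, 0.7640, 0.7087, 0.7095,
    ],
    "japan_ovarian_period": [-0.1198, -0.0775, 0.0411, 0.1562],
    "japan_ovarian_cohort": [
        1.0013, 0.8437, 0.7276, 0.5444, 0.3670, 0.2687, 0.2499, 0.1024,
        -0.0768, -0.2156, -0.3090, -0.4221, -0.8206, -0.9827, -1.2783,
    ],
    "korea_ovarian_age": [
        -1.5340, -1.2848, -1.0276, -0.7083, -0.2547, 0.2250,
        0.5542, 0.6709, 0.6816, 0.8176, 0.8945, 0.9657,
    ],
    "korea_ovarian_period": [-0.3632, -0.0601, 0.1464, 0.2769],
    "korea_ovarian_cohort": [
        0.5938, 0.7791, 0.6567, 0.5252, 0.5175, 0.3379, 0.2407, 0.1146,
        0.1242, -0.1301, -0.2827, -0.3669, -0.7438, -1.0378, -1.3283,
    ],
    "singapore_ovarian_age": [
        -1.7342, -1.9964, -1.2136, -1.1246, -0.1881, 0.2877,
        0.7948, 0.9271, 0.8949, 1.1125, 1.1595, 1.0805,
    ],
    "singapore_ovarian_period": [-0.0857, -0.0019, 0.0051, 0.0825],
    "singapore_ovarian_cohort": [
        0.7966, 0.8288, 0.7477, 0.6114, 0.4375, 0.5753, 0.4153, 0.2764,
        0.0604, 0.1700, 0.0129, -0.2111, -1.2924, -2.0408, -1.3881,
    ],
}

# Spot values for the opt-in real-data reproduction.
PUBLISHED_SPOT_VALUES = {
    "japan_breast_age_20_24": -4.0525,
    "korea_breast_period_2011": 0.3904,
    "singapore_cervical_final_asmr": 2.11,
}
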