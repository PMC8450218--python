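"""Published reference measurements used as test inputs.

Per-animal architectural parameters of the rabbit plantaris across
maturation (eight animals, 29-106 days), the per-age relative model
errors reported for three rabbit calf muscles, and the summary figures
derived from them. These printed values are inputs to the arithmetic
under test (percentage-change and mean +- sample-std aggregation), not
outputs of this package.
"""

PLA_TABLE = {
    "age_d": [29, 29, 33, 64, 64, 78, 86, 106],
    "animal_mass_kg": [0.80, 0.60, 0.76, 2.30, 2.46, 2.00, 3.06, 5.00],
    "belly_length_mm": [50.8, 50.4, 49.1, 78.6, 74.2, 77.5, 74.0, 87.2],
    "fascicle_length_mm": [13.7, 13.8, 15.3, 16.2, 16.0, 16.6, 15.4, 19.0],
    "pennation_deg": [11.6, 10.1, 7.8, 10.8, 12.1, 9.3, 14.6, 13.2],
    "muscle_mass_g": [0.87, 0.71, 0.65, 3.28, 3.13, 2.37, 5.04, 7.00],
    "pcsa_mm2": [60.6, 49.1, 40.1, 192.1, 185.0, 134.9, 310.5, 350.3],
    "free_tendon_mm": [14.5, 14.2, 13.6, 22.6, 22.4, 7.6, 30.5, 26.3],
    "apo_length_mm": [38.7, 37.0, 35.3, 62.6, 61.0, 62.0, 59.5, 68.0],
    "apo_width_mm": [7.7, 7.3, 6.9, 14.6, 14.6, 12.4, 17.6, 20.2],
}

# printed youngest -> oldest percentage changes (rounded to integers)
PLA_PRINTED_CHANGES_PCT = {
    "belly_length_mm": 72,
    "fascicle_length_mm": 39,
    "pennation_deg": 14,
    "muscle_mass_g": 705,
    "pcsa_mm2": 478,
    "apo_width_mm": 162,
    "apo_length_mm": 76,
    "free_tendon_mm": 81,
}

# printed tendon : fascicle length ratios, youngest and oldest animal
TENDON_FASCICLE_RATIOS = (1.06, 1.38)

# per-age relative model errors (%) per muscle, metric -> list, plus the
# printed row aggregates (mean, sample std)
MODEL_ERRORS = {
    "PLA": {
        "apo_length": [5.3, -2.1, -4.8, -4.4, -2.5],
        "apo_width": [3.8, 0.4, 0.4, 0.5, 1.2],
        "muscle_height": [-5.9, 8.5, 2.2, -7.2, 8.1],
        "muscle_mass": [0.4, -3.6, 4.7, -17.3, -6.5],
    },
    "SOL": {
        "apo_length": [15.8, -1.1, -3.5, -4.7, -5.0, 1.4],
        "apo_width": [-15.9, -2.8, -1.9, -2.3, -1.2, -2.5],
        "muscle_height": [-17.2, 2.9, 5.1, 3.5, 4.5, -3.6],
        "muscle_mass": [-17.0, 1.3, 14.5, 14.3, -12.3, -11.8],
    },
    "GM": {
        "apo_length": [13.8, -13.7, -1.7, -4.5],
        "apo_width": [10.5, -0.9, 0.3, -2.1],
        "muscle_height": [-12.7, 19.0, 14.8, 3.8],
        "muscle_mass": [-0.1, -18.8, -3.8, -9.1],
    },
}

PRINTED_AGGREGATES = {
    "PLA": {
        "apo_length": (-1.7, 4.1),
        "apo_width": (1.3, 1.5),
        "muscle_height": (1.2, 7.4),
        "muscle_mass": (-4.5, 8.3),
    },
    "SOL": {
        "apo_length": (0.5, 7.9),
        "apo_width": (-4.4, 5.6),
        "muscle_height": (-0.8, 8.6),
        "muscle_mass": (-1.8, 14.0),
    },
    "GM": {
        "apo_length": (-1.5, 11.5),
        "apo_width": (2.0, 5.8),
        "muscle_height": (6.2, 14.1),
        "muscle_mass": (-8.0, 8.1),
    },
}
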