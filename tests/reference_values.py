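"""Published per-sample Hill numbers from the milk chemotherapy cohort study
whose analysis design this package reimplements. Rows are samples, columns
are diversity orders q = 0..4. Used to cross-check group-mean and t-test
computations against the study's printed summary values."""

PER_SAMPLE_HILL = {
    "pre": {
        "0A": [57, 19.264, 10.856, 8.280, 7.172],
        "2A": [59, 8.227, 3.185, 2.487, 2.257],
        "4A": [59, 7.357, 4.389, 3.644, 3.307],
        "6A": [57, 9.131, 5.772, 4.910, 4.534],
        "10A": [53, 11.532, 7.756, 6.406, 5.715],
        "12A": [51, 3.063, 2.078, 1.867, 1.770],
        "14A": [54, 10.756, 6.167, 5.000, 4.487],
        "16A": [51, 1.514, 1.178, 1.133, 1.117],
    },
    "post": {
        "0B": [61, 28.335, 20.045, 16.248, 14.188],
        "2B": [61, 11.679, 4.406, 3.214, 2.833],
        "4B": [56, 11.432, 6.827, 5.530, 4.938],
        "6B": [48, 5.863, 3.872, 3.389, 3.165],
        "10B": [54, 11.055, 7.525, 6.671, 6.308],
        "12B": [46, 2.851, 2.187, 2.056, 1.986],
        "14B": [57, 6.996, 4.408, 3.651, 3.303],
        "16B": [55, 7.533, 3.871, 3.114, 2.811],
    },
    "healthy": {
        "H1": [46, 22.130, 14.242, 11.362, 10.030],
        "H2A": [42, 15.721, 10.483, 8.897, 8.149],
        "H2B": [44, 18.051, 10.976, 8.642, 7.584],
        "H3": [50, 20.789, 14.849, 12.792, 11.775],
        "H5": [42, 20.522, 14.271, 11.929, 10.777],
        "H6": [52, 22.699, 14.082, 10.243, 8.422],
        "H7": [44, 19.175, 11.909, 9.591, 8.564],
        "H8": [46, 18.674, 11.846, 9.465, 8.314],
        "H10": [48, 15.379, 8.988, 7.048, 6.189],
    },
}

Q_ORDERS = [0.0, 1.0, 2.0, 3.0, 4.0]


def group_values(group: str, q: float) -> list[float]:
    col = Q_ORDERS.index(q)
    return [row[col] for row in PER_SAMPLE_HILL[group].values()]
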