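"""Packaged datasets.

``load_validation_benchmark`` returns the published panel of 19
experimentally tested anti-cancer drug pairs across five cancer types
(pancreatic, non-small cell lung, breast, colorectal, and acute myeloid
leukemia). Each row carries the pair's separation score s_AB on the
corresponding cancer-specific network, the number of overlapping hit
communities, the network-based prediction, and the wet-lab ground truth
(apoptosis assays scored by the Chou–Talalay combination index).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_BENCHMARK = "validation_benchmark.tsv"


def load_validation_benchmark() -> pd.DataFrame:
    """The 19-pair experimental validation panel as a DataFrame.

    Columns: cancer_type, drug_a, drug_b, s_ab (float), overlap (int),
    prediction (bool), ground_truth (bool).
    """
    with resources.files("netcombo.data").joinpath(_BENCHMARK).open("r") as handle:
        frame = pd.read_csv(handle, sep="\t")
    for column in ("prediction", "ground_truth"):
        frame[column] = frame[column].map({"True": True, "False": False, True: True, False: False})
    return frame
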