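"""Bundled signature-model catalogue and per-model significance cutoffs.

The real analysis takes its profile HMMs and cutoffs as inputs; this
catalogue supplies one representative model name per class plus a uniform
default bit-score cutoff so that synthetic data and the pipeline defaults
are self-contained.  A user-supplied model table overrides everything.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

#: One representative signature model per secondary-metabolite class.
CLASS_MODELS: dict[str, str] = {
    "PKS1": "PKS_I_KS",
    "PKS2": "PKS_II_KS",
    "PKS3": "PKS_III_CHS",
    "NRPS": "NRPS_C",
    "indolocarbazole": "IndC",
    "aerobactin_siderophore": "IucA_IucC",
    "butyrolactone": "AfsA",
    "aminoglycoside": "AGly_Ntrans",
    "beta_lactam": "IPNS",
    "terpene": "Terpene_synth_C",
    "lanthipeptide": "LanC",
    "TOMM": "YcaO",
    "phosphonate": "PepM",
}

#: Inverse map: model name -> class.
MODEL_CLASS_MAP: dict[str, str] = {m: c for c, m in CLASS_MODELS.items()}

#: Default per-model significance cutoff (bit score).
DEFAULT_CUTOFFS: dict[str, float] = {m: 50.0 for m in MODEL_CLASS_MAP}


def write_model_table(
    path: str | Path,
    model_class_map: Mapping[str, str] | None = None,
    cutoffs: Mapping[str, float] | None = None,
) -> None:
    mcm = dict(model_class_map or MODEL_CLASS_MAP)
    cut = dict(cutoffs or DEFAULT_CUTOFFS)
    rows = [
        {"model_name": m, "sm_class": c, "min_score": cut.get(m, 0.0)}
        for m, c in sorted(mcm.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_model_table(path: str | Path) -> tuple[dict[str, str], dict[str, float]]:
    """Read a model table TSV -> (model_class_map, cutoffs)."""
    df = pd.read_csv(path, sep="\t")
    mcm = dict(zip(df["model_name"], df["sm_class"]))
    cutoffs = {m: float(s) for m, s in zip(df["model_name"], df["min_score"])}
    return mcm, cutoffs
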