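"""Bundled reference tables: published Malay-vowel articulation and formants.

Two small CSV fixtures ship with the package, taken from a two-subject
(one male, one female) midsagittal MRI study of the six Malay vowels:

* per-frame TTCL/TBCL/LA measurements (mm) over seven consecutive frames
  per vowel, with the published mean/STD/variance columns;
* mean F1/F2 (Hz, with STD) per vowel and gender.

They serve as fixed inputs for reproducing the published summary
statistics, vowel orderings and articulatory–acoustic correlations.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .articulatory import VowelSummary, summarize_frames

_FRAME_COLS = [f"f{i}" for i in range(1, 8)]


def _data_path(name: str):
    return resources.files("tonguetrack.data").joinpath(name)


def load_articulation_table() -> pd.DataFrame:
    """Per-frame articulation table (36 rows: vowel x gender x parameter)."""
    with resources.as_file(_data_path("malay_vowel_articulation.csv")) as p:
        return pd.read_csv(p)


def load_formant_table(long: bool = False) -> pd.DataFrame:
    """Published formant means. ``long=True`` yields vowel/gender/f1/f2 rows."""
    with resources.as_file(_data_path("malay_vowel_formants.csv")) as p:
        df = pd.read_csv(p)
    if not long:
        return df
    rows = []
    for _, row in df.iterrows():
        for gender, tag in (("M", "male"), ("F", "female")):
            rows.append({"vowel": row["vowel"], "gender": gender,
                         "f1": row[f"f1_{tag}"], "f2": row[f"f2_{tag}"]})
    return pd.DataFrame(rows)


def frame_values(row: pd.Series) -> list[float]:
    """The seven per-frame measurements of one table row."""
    return [float(row[c]) for c in _FRAME_COLS]


def summaries_from_table(df: pd.DataFrame | None = None) -> list[VowelSummary]:
    """Recompute VowelSummary objects from the per-frame columns."""
    df = load_articulation_table() if df is None else df
    return [summarize_frames(frame_values(row), row["vowel"], row["gender"],
                             row["parameter"])
            for _, row in df.iterrows()]


def articulation_means(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recomputed per-vowel means as a vowel/gender/parameter/mean frame."""
    summaries = summaries_from_table(df)
    return pd.DataFrame([{"vowel": s.vowel, "gender": s.gender,
                          "parameter": s.parameter, "mean": s.mean}
                         for s in summaries])
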