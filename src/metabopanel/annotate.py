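"""Precursor-mass annotation against a user-supplied reference compound list.

Features are matched to reference compounds by signed mass accuracy in parts
per million; candidates within the tolerance (default 20 ppm, inclusive) are
returned sorted by absolute deviation.  Matching is precursor-only: no MS2
fragment evidence is modelled, and candidate lists carry an explicit
``"precursor-only"`` evidence tag.  Taxonomy fields (super class / class /
direct parent) are passed through from the reference list.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

EVIDENCE = "precursor-only"


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceCompound:
    name: str
    theoretical_mz: float
    super_class: str | None = None
    compound_class: str | None = None
    direct_parent: str | None = None

    def __post_init__(self) -> None:
        if self.theoretical_mz <= 0:
            raise AnnotationError(
                f"theoretical m/z must be positive for {self.name!r}"
            )


def mass_delta_ppm(observed_mz: float, theoretical_mz: float) -> float:
    """Signed mass deviation (observed - theoretical) / theoretical * 1e6."""
    if observed_mz <= 0 or theoretical_mz <= 0:
        raise AnnotationError("m/z values must be positive")
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6


@dataclass(frozen=True)
class Candidate:
    name: str
    theoretical_mz: float
    delta_ppm: float
    super_class: str | None = None
    compound_class: str | None = None
    direct_parent: str | None = None
    evidence: str = EVIDENCE


def match_features(
    features: Sequence[tuple[float, float]],
    references: Sequence[ReferenceCompound],
    tolerance_ppm: float = 20.0,
) -> list[list[Candidate]]:
    """Per-feature candidate lists: all references with |delta| <= tolerance
    (boundary inclusive), sorted by absolute deviation."""
    if not references:
        raise AnnotationError("empty reference compound list")
    if tolerance_ppm <= 0:
        raise AnnotationError("tolerance_ppm must be positive")
    out: list[list[Candidate]] = []
    for _rt, mz in features:
        cands = []
        for ref in references:
            d = mass_delta_ppm(mz, ref.theoretical_mz)
            if abs(d) <= tolerance_ppm:
                cands.append(
                    Candidate(
                        name=ref.name,
                        theoretical_mz=ref.theoretical_mz,
                        delta_ppm=d,
                        super_class=ref.super_class,
                        compound_class=ref.compound_class,
                        direct_parent=ref.direct_parent,
                    )
                )
        cands.sort(key=lambda c: abs(c.delta_ppm))
        out.append(cands)
    return out


def read_reference_list(path: str | Path) -> list[ReferenceCompound]:
    """Delimited text with columns name, mz and optional taxonomy columns
    (super_class, class, direct_parent)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"name", "mz"}
    if required - set(df.columns):
        raise AnnotationError("reference list needs 'name' and 'mz' columns")
    refs = []
    for _, row in df.iterrows():
        refs.append(
            ReferenceCompound(
                name=str(row["name"]),
                theoretical_mz=float(row["mz"]),
                super_class=row.get("super_class"),
                compound_class=row.get("class"),
                direct_parent=row.get("direct_parent"),
            )
        )
    return refs


def annotate_table(
    diff_table: pd.DataFrame,
    references: Sequence[ReferenceCompound],
    tolerance_ppm: float = 20.0,
) -> pd.DataFrame:
    """Join the best candidate (smallest |delta_ppm|) onto a differential
    table with ``rt``/``mz`` columns; unmatched features get empty fields."""
    feats = list(zip(diff_table["rt"], diff_table["mz"]))
    matches = match_features(feats, references, tolerance_ppm)
    best = [m[0] if m else None for m in matches]
    out = diff_table.copy()
    out["annotation"] = [b.name if b else "" for b in best]
    out["delta_ppm"] = [b.delta_ppm if b else float("nan") for b in best]
    out["super_class"] = [b.super_class if b else "" for b in best]
    out["class"] = [b.compound_class if b else "" for b in best]
    out["direct_parent"] = [b.direct_parent if b else "" for b in best]
    out["evidence"] = [EVIDENCE if b else "" for b in best]
    return out
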