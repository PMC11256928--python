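"""Reading ranked PSM score tables and the top-two score extraction rules.

Input dialects (plain TSV with a required header):

* long form — columns ``spectrum_id``, ``peptide_pair_id``, ``xl_position_id``,
  ``rank``, ``score``; one row per candidate PSM.  ``rank`` may be omitted, in
  which case candidates are ordered by descending score (stable by
  ``peptide_pair_id``).
* wide form — columns ``s1``, ``s2``; one row per spectrum, ``s2`` empty or
  ``NA`` when the spectrum had a single eligible candidate.

Extraction follows the XL-MS/MS convention for the top two candidates per
spectrum: when ranks 1 and 2 carry the same (sorted) peptide pair and differ
only in the cross-link residue position, rank 2 is redundant and the rank-3
candidate, if any, is promoted to the second position; a spectrum with a
single eligible candidate gets a missing second score.  The fraction of
spectra with missing second scores, ``v_phi``, is carried by the dataset and
enters the mixture-weight constraint set as a constant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .sn import SNParams

__all__ = [
    "FormatError",
    "PSMRecord",
    "ScoreDataset",
    "extract_top_two",
    "compute_v_phi",
    "read_ranked_tsv",
    "read_scores_tsv",
    "write_scores_tsv",
    "write_model_json",
    "read_model_json",
]

MISSING = float("nan")


class FormatError(ValueError):
    """Malformed input table."""


@dataclass(frozen=True)
class PSMRecord:
    spectrum_id: str
    peptide_pair_id: str
    xl_position_id: str
    score: float
    rank: int


@dataclass
class ScoreDataset:
    """Paired top/second PSM scores per spectrum; NaN marks a missing s2."""

    s1: np.ndarray
    s2: np.ndarray

    def __post_init__(self) -> None:
        self.s1 = np.asarray(self.s1, dtype=float)
        self.s2 = np.asarray(self.s2, dtype=float)
        if self.s1.shape != self.s2.shape or self.s1.ndim != 1:
            raise ValueError("s1 and s2 must be 1-d arrays of equal length")
        if np.isnan(self.s1).any():
            raise ValueError("s1 may not contain missing values")

    @property
    def n(self) -> int:
        return self.s1.size

    @property
    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.s2)

    @property
    def s2_observed(self) -> np.ndarray:
        return self.s2[self.observed_mask]

    @property
    def v_phi(self) -> float:
        """Fraction of spectra with a missing second score."""
        return compute_v_phi(self)


def compute_v_phi(ds: ScoreDataset) -> float:
    if ds.n == 0:
        raise ValueError("empty dataset has no defined v_phi")
    return float(np.isnan(ds.s2).mean())


def _order_candidates(cands: list[PSMRecord]) -> list[PSMRecord]:
    if all(c.rank > 0 for c in cands):
        ranks = [c.rank for c in cands]
        if len(set(ranks)) != len(ranks):
            raise FormatError(
                f"duplicate (spectrum, rank) for spectrum {cands[0].spectrum_id!r}"
            )
        out = sorted(cands, key=lambda c: c.rank)
    else:
        # no rank information: descending score, stable by peptide_pair_id
        out = sorted(cands, key=lambda c: (-c.score, c.peptide_pair_id))
    scores = [c.score for c in out]
    if any(a < b for a, b in zip(scores, scores[1:])):
        raise FormatError(
            f"scores increase with rank for spectrum {out[0].spectrum_id!r}"
        )
    return out


def extract_top_two(records: Iterable[PSMRecord]) -> ScoreDataset:
    """Reduce ranked candidate lists to one (s1, s2) pair per spectrum.

    Applies the duplicate-pair promotion rule: if the top two candidates share
    a peptide pair but differ in cross-link position, the second is dropped
    and the third (if present) becomes s2.
    """
    by_spectrum: dict[str, list[PSMRecord]] = {}
    for rec in records:
        by_spectrum.setdefault(rec.spectrum_id, []).append(rec)
    s1, s2 = [], []
    for cands in by_spectrum.values():
        cands = _order_candidates(cands)
        top = cands[0]
        rest = cands[1:]
        if (
            rest
            and rest[0].peptide_pair_id == top.peptide_pair_id
            and rest[0].xl_position_id != top.xl_position_id
        ):
            rest = rest[1:]  # same pair, different link site: promote rank 3
        s1.append(top.score)
        s2.append(rest[0].score if rest else MISSING)
    return ScoreDataset(s1=np.array(s1, dtype=float), s2=np.array(s2, dtype=float))


_LONG_COLUMNS = ("spectrum_id", "peptide_pair_id", "xl_position_id", "score")


def read_ranked_tsv(path) -> list[PSMRecord]:
    """Read long-form candidate table; ``rank`` column optional (0 = absent)."""
    df = pd.read_csv(path, sep="\t", dtype={"spectrum_id": str})
    missing = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"long-form TSV missing columns: {missing}")
    has_rank = "rank" in df.columns
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            score = float(row.score)
            rank = int(row.rank) if has_rank else 0
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: malformed row at line {i}: {exc}") from exc
        if has_rank and rank < 1:
            raise FormatError(f"{path}: line {i}: rank must be >= 1")
        records.append(
            PSMRecord(
                spectrum_id=str(row.spectrum_id),
                peptide_pair_id=str(row.peptide_pair_id),
                xl_position_id=str(row.xl_position_id),
                score=score,
                rank=rank,
            )
        )
    # every spectrum must have a rank-1 row when ranks are given
    if has_rank:
        tops = {r.spectrum_id for r in records if r.rank == 1}
        for r in records:
            if r.spectrum_id not in tops:
                raise FormatError(
                    f"spectrum {r.spectrum_id!r} has no rank-1 candidate"
                )
    return records


def read_scores_tsv(path) -> ScoreDataset:
    """Read wide-form (s1, s2) table; empty or 'NA' second score = missing."""
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""])
    if "s1" not in df.columns or "s2" not in df.columns:
        raise FormatError("wide-form TSV must have columns s1 and s2")
    if df["s1"].isna().any():
        line = int(df.index[df["s1"].isna()][0]) + 2
        raise FormatError(f"{path}: missing s1 at line {line}")
    return ScoreDataset(
        s1=df["s1"].to_numpy(dtype=float), s2=df["s2"].to_numpy(dtype=float)
    )


def write_scores_tsv(ds: ScoreDataset, path) -> None:
    pd.DataFrame({"s1": ds.s1, "s2": ds.s2}).to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )


# ---------------------------------------------------------------------------
# model JSON serialization (canonical-form parameters; lossless round trip)
# ---------------------------------------------------------------------------


def _theta_to_json(theta) -> dict:
    return {
        name: {"mu": p.mu, "sigma": p.sigma, "lam": p.lam}
        for name, p in theta.items()
    }


def write_model_json(model, path, *, loglik=None, metadata=None) -> None:
    """Serialize a fitted one- or two-sample model (see :mod:`xlfdr.model`)."""
    from .model import OneSampleModel, TwoSampleModel  # local import: avoid cycle

    doc: dict = {"components": _theta_to_json(model.theta)}
    if isinstance(model, TwoSampleModel):
        doc["kind"] = "two_sample"
        doc["w"] = dict(zip(("C", "J1", "I1"), (float(x) for x in model.w)))
        doc["v"] = dict(
            zip(("C", "J1", "J2", "I1", "I2"), (float(x) for x in model.v))
        )
        doc["v_phi"] = float(model.v_phi)
    elif isinstance(model, OneSampleModel):
        doc["kind"] = "one_sample"
        doc["w"] = dict(zip(("C", "J1", "I1"), (float(x) for x in model.w)))
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    if loglik is not None:
        doc["loglik"] = float(loglik)
    if metadata is not None:
        doc["fit"] = metadata
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_model_json(path):
    from .model import OneSampleModel, TwoSampleModel

    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    theta = {
        name: SNParams(mu=d["mu"], sigma=d["sigma"], lam=d["lam"])
        for name, d in doc["components"].items()
    }
    if doc.get("kind") == "two_sample":
        w = np.array([doc["w"][k] for k in ("C", "J1", "I1")])
        v = np.array([doc["v"][k] for k in ("C", "J1", "J2", "I1", "I2")])
        return TwoSampleModel(theta=theta, w=w, v=v, v_phi=doc["v_phi"])
    if doc.get("kind") == "one_sample":
        w = np.array([doc["w"][k] for k in ("C", "J1", "I1")])
        return OneSampleModel(theta=theta, w=w)
    raise FormatError(f"{path}: unknown model kind {doc.get('kind')!r}")
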