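"""HLA class-I neoantigen candidate enumeration and strong-binder filtering.

Candidates are 8-11-mer peptides from the three-frame translation of a
junction window, kept only when their codon span crosses the junction.
Binding is scored through a pluggable predictor interface; percent rank
compares a candidate's score with a seeded background of random
natural-frequency peptides, and a strong binder is a percent rank below 0.5.

The default predictor is a deterministic mock — allele-specific position
weights drawn from a seeded generator, lower score meaning stronger
predicted binding — so the whole filter chain is reproducible without any
external affinity tool. An external predictor can be supplied through the
same two-argument interface.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Optional, Protocol, Sequence

import numpy as np
import pandas as pd

from .peptides import JunctionWindow
from .simulate import AA_ALPHABET, AA_FREQ

_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}


class BindingPredictor(Protocol):
    """Affinity predictor interface: lower score = stronger predicted binder.

    Implementations must be deterministic for fixed (peptide, allele)."""

    def predict(self, peptide: str, allele: str) -> float: ...


@dataclass(frozen=True)
class NeoantigenCandidate:
    junction_id: str
    peptide: str
    allele: str
    patient_id: str
    affinity_score: float
    percent_rank: float
    strong_binder: bool


class PositionWeightPredictor:
    """Deterministic mock affinity predictor.

    Per (allele, peptide length) a position x amino-acid weight matrix is
    drawn from a generator seeded by a stable hash of the allele name, so
    different alleles have different anchor preferences while every call is
    reproducible. The score is the negated mean positional weight: lower is
    stronger.
    """

    def __init__(self, seed: int = 0):
        self.seed = seed
        self._cache: dict[tuple[str, int], np.ndarray] = {}

    def _weights(self, allele: str, length: int) -> np.ndarray:
        key = (allele, length)
        if key not in self._cache:
            h = zlib.crc32(f"{allele}|{length}".encode()) & 0x7FFFFFFF
            rng = np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(h,)))
            self._cache[key] = rng.normal(0.0, 1.0, size=(length, len(AA_ALPHABET)))
        return self._cache[key]

    def predict(self, peptide: str, allele: str) -> float:
        w = self._weights(allele, len(peptide))
        idx = [_AA_INDEX[a] for a in peptide]
        return float(-w[np.arange(len(peptide)), idx].mean())


def enumerate_candidates(
    window: JunctionWindow, lengths: Sequence[int] = (8, 9, 10, 11)
) -> list[str]:
    """All stop-free 8-11-mers from 3-frame translation whose codon span
    covers the junction midpoint; deduplicated and sorted."""
    from Bio.Seq import Seq

    mid = window.midpoint
    out: set[str] = set()
    for frame in range(3):
        n_codons = (len(window.sequence) - frame) // 3
        if n_codons == 0:
            continue
        aa = str(Seq(window.sequence[frame : frame + 3 * n_codons]).translate())
        for k in lengths:
            for i in range(0, len(aa) - k + 1):
                pep = aa[i : i + k]
                if "*" in pep:
                    continue
                nt_s = frame + 3 * i
                nt_e = frame + 3 * (i + k)
                if nt_s < mid < nt_e:
                    out.add(pep)
    return sorted(out)


def random_background(
    n: int, length: int, rng: np.random.Generator
) -> list[str]:
    """Random peptides drawn with natural amino-acid frequencies."""
    aa = np.array(list(AA_ALPHABET))
    block = rng.choice(aa, size=(n, length), p=AA_FREQ)
    return ["".join(row) for row in block]


def percent_rank(
    score: float,
    allele: str,
    background: Sequence[str],
    predictor: BindingPredictor,
) -> float:
    """Percentile of a score against a background peptide set.

    rank = 100 * (#background with better-or-equal score) / background size;
    lower rank means a stronger binder (lower score)."""
    if not background:
        raise ValueError("background must be non-empty")
    bg = np.array([predictor.predict(p, allele) for p in background])
    return float(100.0 * (bg <= score).sum() / len(bg))


class _RankTable:
    """Sorted background scores per (allele, length) for fast rank lookup."""

    def __init__(self, predictor: BindingPredictor, background_size: int, seed: int):
        self.predictor = predictor
        self.background_size = background_size
        self.seed = seed
        self._scores: dict[tuple[str, int], np.ndarray] = {}

    def rank(self, score: float, allele: str, length: int) -> float:
        key = (allele, length)
        if key not in self._scores:
            h = zlib.crc32(f"bg|{allele}|{length}".encode()) & 0x7FFFFFFF
            rng = np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(h,)))
            bg = random_background(self.background_size, length, rng)
            self._scores[key] = np.sort(
                np.array([self.predictor.predict(p, allele) for p in bg])
            )
        s = self._scores[key]
        return float(100.0 * np.searchsorted(s, score, side="right") / len(s))


def filter_strong_binders(
    candidates: Iterable[tuple[str, str]],
    serotypes: dict[str, Sequence[str]],
    predictor: Optional[BindingPredictor] = None,
    threshold: float = 0.5,
    background_size: int = 10_000,
    seed: int = 0,
    patients: Optional[dict[str, Sequence[str]]] = None,
    return_all: bool = False,
) -> list[NeoantigenCandidate]:
    """Score (junction_id, peptide) candidates against patient serotypes.

    ``patients`` optionally maps junction_id -> patient ids carrying it;
    by default every candidate is evaluated for every patient. A missing
    serotype for a requested patient is a hard error. Returns strong binders
    (percent rank < threshold); pass ``return_all`` for every scored record.
    """
    predictor = predictor or PositionWeightPredictor(seed=seed)
    table = _RankTable(predictor, background_size, seed)
    cand = list(candidates)
    out: list[NeoantigenCandidate] = []
    for junction_id, pep in cand:
        patient_ids = (
            list(patients.get(junction_id, [])) if patients is not None else list(serotypes)
        )
        for pid in patient_ids:
            if pid not in serotypes:
                raise KeyError(f"no HLA serotype for patient {pid}")
            for allele in serotypes[pid]:
                score = predictor.predict(pep, allele)
                rank = table.rank(score, allele, len(pep))
                strong = rank < threshold
                if strong or return_all:
                    out.append(
                        NeoantigenCandidate(
                            junction_id=junction_id,
                            peptide=pep,
                            allele=allele,
                            patient_id=pid,
                            affinity_score=score,
                            percent_rank=rank,
                            strong_binder=strong,
                        )
                    )
    return out


def candidates_to_frame(records: Sequence[NeoantigenCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "junction_id": r.junction_id,
                "peptide": r.peptide,
                "allele": r.allele,
                "patient_id": r.patient_id,
                "affinity_score": r.affinity_score,
                "percent_rank": r.percent_rank,
                "strong_binder": r.strong_binder,
            }
            for r in records
        ],
        columns=[
            "junction_id",
            "peptide",
            "allele",
            "patient_id",
            "affinity_score",
            "percent_rank",
            "strong_binder",
        ],
    )
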