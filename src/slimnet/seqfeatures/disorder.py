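"""Intrinsic disorder as a sliding-window propensity profile.

The built-in proxy applies the TOP-IDP residue scale (Campen et al. 2008,
Protein Pept Lett 15:956) with a 21-residue window and a threshold at the
scale's neutral point (0.0): positive smoothed propensity means
disorder-promoting context.  Precomputed per-residue scores (e.g. exported
from a disorder database) can be imported from TSV instead and take
precedence over the proxy.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np

from ..records import ProteinRecord

# TOP-IDP disorder propensity scale; > 0 disorder-promoting.
TOP_IDP: dict[str, float] = {
    "A": 0.06, "R": 0.180, "N": 0.007, "D": 0.192, "C": 0.02,
    "Q": 0.318, "E": 0.736, "G": 0.166, "H": 0.303, "I": -0.486,
    "L": -0.326, "K": 0.586, "M": -0.397, "F": -0.697, "P": 0.987,
    "S": 0.341, "T": 0.059, "V": -0.121, "W": -0.884, "Y": -0.510,
}

DEFAULT_WINDOW = 21
DEFAULT_THRESHOLD = 0.0


class DisorderConfigError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class DisorderProfile:
    protein: str
    raw: np.ndarray
    smoothed: np.ndarray
    calls: np.ndarray
    threshold: float

    def fraction_disordered(self, start: int, end: int) -> float:
        """Fraction of residues in 1-based inclusive ``start..end`` called disordered."""
        return float(np.mean(self.calls[start - 1 : end]))


def _windowed_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Mean over a centered window, truncated at the termini."""
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    n = len(values)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def score_disorder(
    protein: ProteinRecord,
    scale: Mapping[str, float] | None = None,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
) -> DisorderProfile:
    """Per-residue propensity, windowed mean and boolean disorder calls."""
    if window < 1 or window % 2 == 0:
        raise DisorderConfigError(f"window must be odd and >= 1, got {window}")
    scale = dict(scale) if scale is not None else dict(TOP_IDP)
    missing = set("ACDEFGHIKLMNPQRSTVWY") - set(scale)
    if missing:
        raise DisorderConfigError(f"scale missing residues {sorted(missing)}")
    scale.setdefault("X", float(np.mean([scale[a] for a in "ACDEFGHIKLMNPQRSTVWY"])))
    raw = np.array([scale[a] for a in protein.sequence], dtype=float)
    smoothed = _windowed_mean(raw, window)
    return DisorderProfile(
        protein=protein.accession,
        raw=raw,
        smoothed=smoothed,
        calls=smoothed >= threshold,
        threshold=threshold,
    )


def load_disorder_tsv(
    path: str | Path, protein: ProteinRecord, threshold: float = 0.5
) -> DisorderProfile:
    """Import per-residue disorder scores (columns: accession, position, score).

    Imported scores are treated as both raw and smoothed signal; the call
    threshold defaults to 0.5 as is conventional for probability-like scores.
    """
    scores = np.full(len(protein), np.nan)
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            if row["accession"] != protein.accession:
                continue
            pos = int(row["position"])
            if not (1 <= pos <= len(protein)):
                raise DisorderConfigError(
                    f"{path}: position {pos} outside {protein.accession}"
                )
            scores[pos - 1] = float(row["score"])
    if np.isnan(scores).any():
        raise DisorderConfigError(
            f"{path}: incomplete disorder profile for {protein.accession}"
        )
    return DisorderProfile(
        protein=protein.accession,
        raw=scores,
        smoothed=scores.copy(),
        calls=scores >= threshold,
        threshold=threshold,
    )
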