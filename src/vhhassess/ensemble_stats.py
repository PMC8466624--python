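"""Per-position PB statistics over model ensembles.

Given the PB strings of an ensemble of models of one query, these routines
compute the per-position PB frequency profile, the equivalent number of PBs

    Neq = exp(-sum_x f_x ln f_x)          (1 <= Neq <= 16)

the signed difference Delta-Neq between two ensembles, and the per-position
L1 profile distance

    dPB = sum_x |f1_x - f2_x|             (0 <= dPB <= 2).

Undefined letters (Z) are excluded from the counts: the sums run over the 16
PB letters only.  Positions where no model contributes a defined letter are
marked "no data" and propagate NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pb_alphabet import PB_LETTERS, UNDEFINED

_INDEX = {c: i for i, c in enumerate(PB_LETTERS)}


@dataclass
class PBFrequencyProfile:
    """Per-position PB letter counts and frequencies for an ensemble.

    Attributes
    ----------
    counts : ndarray of int, shape (L, 16)
        Letter counts per position, columns ordered a..p.
    """

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[1] != 16 or (c < 0).any():
            raise ValueError("counts must be a non-negative (L, 16) array")
        self.counts = c.astype(np.int64)

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def support_count(self) -> np.ndarray:
        """Number of non-Z observations per position."""
        return self.counts.sum(axis=1)

    @property
    def frequencies(self) -> np.ndarray:
        """(L, 16) probability vectors; rows of NaN where support is zero."""
        n = self.support_count.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.counts / n[:, None]
        f[n == 0] = np.nan
        return f


def pb_frequency_profile(ensemble) -> PBFrequencyProfile:
    """Count PB letters per position over an ensemble of PB strings."""
    seqs = list(ensemble)
    if not seqs:
        raise ValueError("empty ensemble")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("all PB sequences must have equal length")
    counts = np.zeros((L, 16), dtype=np.int64)
    for s in seqs:
        for i, c in enumerate(s):
            if c == UNDEFINED:
                continue
            try:
                counts[i, _INDEX[c]] += 1
            except KeyError:
                raise ValueError(f"invalid PB letter {c!r} at position {i + 1}")
    return PBFrequencyProfile(counts)


def neq_profile(profile: PBFrequencyProfile) -> np.ndarray:
    """Equivalent number of PBs per position (NaN where no data).

    Neq = exp(Shannon entropy, natural log) of the per-position PB
    distribution; 1 when a single letter is observed, 16 for the uniform
    distribution over the whole alphabet.
    """
    f = profile.frequencies
    with np.errstate(invalid="ignore", divide="ignore"):
        plogp = np.where(f > 0, f * np.log(f), 0.0)
    neq = np.exp(-plogp.sum(axis=1))
    neq[profile.support_count == 0] = np.nan
    return neq


def delta_neq(profile_a: PBFrequencyProfile,
              profile_b: PBFrequencyProfile) -> np.ndarray:
    """Signed per-position Neq(A) - Neq(B); NaN where either lacks data."""
    if len(profile_a) != len(profile_b):
        raise ValueError("profiles must have equal length")
    return neq_profile(profile_a) - neq_profile(profile_b)


def delta_pb(profile_a: PBFrequencyProfile,
             profile_b: PBFrequencyProfile) -> np.ndarray:
    """Per-position L1 distance between two PB profiles, in [0, 2].

    0 means identical per-position distributions; 2 means disjoint support
    (totally different local conformations).  NaN where either profile has
    no data.
    """
    if len(profile_a) != len(profile_b):
        raise ValueError("profiles must have equal length")
    fa, fb = profile_a.frequencies, profile_b.frequencies
    return np.abs(fa - fb).sum(axis=1)


def pb_map(profile: PBFrequencyProfile, as_frequency: bool = True) -> pd.DataFrame:
    """PB map: positions x 16 letters matrix, TSV-serialisable.

    Rows are the 1-based positions; columns the letters a..p.  With
    ``as_frequency`` the rows sum to 1 at supported positions (NaN rows
    where no data); otherwise raw counts are returned.
    """
    data = profile.frequencies if as_frequency else profile.counts
    return pd.DataFrame(
        data,
        index=pd.RangeIndex(1, len(profile) + 1, name="position"),
        columns=list(PB_LETTERS),
    )


def write_pb_map(profile: PBFrequencyProfile, path, as_frequency: bool = True) -> None:
    pb_map(profile, as_frequency=as_frequency).to_csv(path, sep="\t")


def read_pb_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="position")


def profile_from_pb_map_counts(df: pd.DataFrame) -> PBFrequencyProfile:
    """Rebuild a profile from a counts PB map written by :func:`write_pb_map`."""
    return PBFrequencyProfile(df[list(PB_LETTERS)].to_numpy())
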