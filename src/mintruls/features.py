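"""Per-entity sequence features feeding the similarity kernels.

Four feature families are computed per miRNA or target site:

* minimum free energy (MFE) of the folded sequence, kcal/mol (<= 0) --
  a stable intramolecular structure competes with duplex formation;
* site accessibility -- the mean probability that a position is unpaired,
  so available for miRNA binding;
* AU fraction -- low GC (high AU) near a site correlates with openness;
* simple-sequence-repeat (SSR) content -- tandem runs of 2-4 nt motifs,
  counted as a motif -> repeat-count vector.

Folding is abstracted behind :class:`FoldingProvider`.  The bundled
:class:`NussinovProvider` is a self-contained maximum-pairing dynamic
program with fixed per-pair energies (GC -3, AU -2, GU -1 kcal/mol, min
hairpin loop 3); :class:`ViennaRNAProvider` wraps the RNAfold/RNAplfold
command-line tools when they are available.  Kernels consume only pairwise
differences of these scalars, so any internally consistent provider
preserves the structure of the method.
"""

from __future__ import annotations

import functools
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np
import pandas as pd

from .data_model import InteractionMatrix

__all__ = [
    "FoldingProvider",
    "NussinovProvider",
    "ViennaRNAProvider",
    "FeatureTable",
    "compute_free_energy",
    "compute_accessibility",
    "compute_au_content",
    "extract_ssrs",
    "build_interaction_profiles",
]

_PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}
_MIN_HAIRPIN_LOOP = 3


class FoldingProvider(Protocol):
    """Deterministic RNA secondary-structure engine."""

    name: str

    def fold(self, seq: str) -> tuple[float, str]:
        """Return (mfe in kcal/mol, dot-bracket structure)."""
        ...

    def accessibility(self, seq: str, window: int) -> float:
        """Mean per-position unpaired probability, in [0, 1]."""
        ...


def _check_rna(seq: str, allow_n: bool = True) -> None:
    allowed = set("ACGUN") if allow_n else set("ACGU")
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"invalid letters {sorted(bad)} in sequence")
    if not seq:
        raise ValueError("empty sequence")


@functools.lru_cache(maxsize=16384)
def _nussinov_fold(seq: str) -> tuple[float, str]:
    """Energy-minimizing maximum-pairing fold with simple pair energies.

    N never pairs.  O(n^3); sequences here are <= ~50 nt.
    """
    n = len(seq)
    E = [[0.0] * n for _ in range(n)]
    for span in range(_MIN_HAIRPIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            row_i = E[i]
            best = E[i + 1][j]
            if row_i[j - 1] < best:
                best = row_i[j - 1]
            pe = _PAIR_ENERGY.get((seq[i], seq[j]))
            if pe is not None:
                v = E[i + 1][j - 1] + pe
                if v < best:
                    best = v
            for k in range(i + 1, j):
                v = row_i[k] + E[k + 1][j]
                if v < best:
                    best = v
            row_i[j] = best

    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= _MIN_HAIRPIN_LOOP:
            continue
        e = E[i][j]
        if e == E[i + 1][j]:
            stack.append((i + 1, j))
            continue
        if e == E[i][j - 1]:
            stack.append((i, j - 1))
            continue
        pe = _PAIR_ENERGY.get((seq[i], seq[j]))
        if pe is not None and e == E[i + 1][j - 1] + pe:
            structure[i], structure[j] = "(", ")"
            stack.append((i + 1, j - 1))
            continue
        for k in range(i + 1, j):
            if e == E[i][k] + E[k + 1][j]:
                stack.append((i, k))
                stack.append((k + 1, j))
                break
    return E[0][n - 1] if n else 0.0, "".join(structure)


@dataclass(frozen=True)
class NussinovProvider:
    """Bundled self-contained folding engine.

    Pair energies GC -3, AU -2, GU -1 kcal/mol; minimum hairpin loop of 3
    unpaired bases.  Accessibility is the fraction of unpaired positions
    in the MFE structure (the window argument is validated but the
    structure is global, so it does not alter the value).
    """

    name: str = "nussinov"

    def fold(self, seq: str) -> tuple[float, str]:
        _check_rna(seq)
        return _nussinov_fold(seq)

    def accessibility(self, seq: str, window: int) -> float:
        _check_rna(seq)
        if window < 1 or window > len(seq):
            raise ValueError(f"window must be in [1, {len(seq)}], got {window}")
        _, structure = _nussinov_fold(seq)
        return structure.count(".") / len(structure)


@dataclass(frozen=True)
class ViennaRNAProvider:
    """Thermodynamic provider shelling out to RNAfold / RNAplfold."""

    name: str = "viennarna"

    @staticmethod
    def available() -> bool:
        return shutil.which("RNAfold") is not None

    def fold(self, seq: str) -> tuple[float, str]:
        _check_rna(seq)
        out = subprocess.run(
            ["RNAfold", "--noPS"], input=seq + "\n", text=True,
            capture_output=True, check=True,
        ).stdout.splitlines()
        # second line: "....((..))... ( -1.20)"
        struct_line = out[1]
        structure, _, energy = struct_line.rpartition(" (")
        return float(energy.rstrip(")").strip()), structure.strip()

    def accessibility(self, seq: str, window: int) -> float:
        _check_rna(seq)
        if window < 1 or window > len(seq):
            raise ValueError(f"window must be in [1, {len(seq)}], got {window}")
        with tempfile.TemporaryDirectory() as tmp:
            subprocess.run(
                ["RNAplfold", "-W", str(min(window * 7, len(seq))), "-u", "1"],
                input=seq + "\n", text=True, capture_output=True,
                check=True, cwd=tmp,
            )
            lunp = next(Path(tmp).glob("*_lunp"))
            probs = []
            for line in lunp.read_text().splitlines():
                if line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) >= 2 and fields[1] != "NA":
                    probs.append(float(fields[1]))
        return float(np.mean(probs))


def compute_free_energy(seq: str, provider: FoldingProvider | None = None) -> float:
    """Minimum free energy of the folded sequence, kcal/mol (<= 0).

    N positions never pair; a sequence admitting no base pairs folds to
    the open chain at 0 kcal/mol.
    """
    provider = provider or NussinovProvider()
    _check_rna(seq)
    mfe, _ = provider.fold(seq)
    return float(min(mfe, 0.0))


def compute_accessibility(seq: str, provider: FoldingProvider | None = None,
                          window: int = 10) -> float:
    """Mean unpaired probability across the sequence, in [0, 1]."""
    provider = provider or NussinovProvider()
    if window > len(seq):
        raise ValueError(f"window {window} exceeds sequence length {len(seq)}")
    return float(provider.accessibility(seq, window))


def compute_au_content(seq: str) -> float:
    """Fraction of A/U among non-N positions; complements GC content."""
    _check_rna(seq)
    informative = len(seq) - seq.count("N")
    if informative == 0:
        raise ValueError("AU content undefined for an all-N sequence")
    return (seq.count("A") + seq.count("U")) / informative


def _is_primitive(motif: str) -> bool:
    """True unless the motif is itself a tandem repeat of a shorter unit."""
    L = len(motif)
    for p in range(1, L):
        if L % p == 0 and motif == motif[:p] * (L // p):
            return False
    return True


def extract_ssrs(seq: str, min_repeats: int = 3,
                 motif_lengths: tuple[int, ...] = (2, 3, 4)) -> dict[str, int]:
    """Count tandem simple-sequence-repeat runs per motif.

    A greedy left-to-right scan per motif length finds maximal tandem runs;
    a run of r >= ``min_repeats`` contiguous copies of motif M contributes
    r to the count under key M.  Only primitive motifs count (homopolymers
    such as "AA", and phase-redundant motifs such as "ACAC", are excluded
    -- their runs are already reported at the shorter period).  Runs for
    different motif lengths are scanned independently.
    """
    if min_repeats < 2:
        raise ValueError("min_repeats must be >= 2")
    _check_rna(seq)
    counts: dict[str, int] = {}
    for L in motif_lengths:
        i = 0
        n = len(seq)
        while i + L * min_repeats <= n:
            motif = seq[i : i + L]
            if "N" in motif or not _is_primitive(motif):
                i += 1
                continue
            r = 1
            while seq[i + r * L : i + (r + 1) * L] == motif:
                r += 1
            if r >= min_repeats:
                counts[motif] = counts.get(motif, 0) + r
                i += r * L
            else:
                i += 1
    return counts


def build_interaction_profiles(matrix: InteractionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Binary interaction profiles: rows for miRNAs, columns for sites.

    Returns (IP_m, IP_t) where IP_m[i] is row i of A (length n_t) and
    IP_t[j] is column j of A (length n_m).
    """
    A = matrix.A
    return A.copy(), A.T.copy()


@dataclass
class FeatureTable:
    """Scalar features and SSR count vectors for one entity set."""

    entity_ids: list[str]
    mfe: np.ndarray
    au_fraction: np.ndarray
    ssr_counts: pd.DataFrame  # entities x motifs, nonnegative ints
    accessibility: np.ndarray | None = None
    provider_name: str = "nussinov"

    def __post_init__(self) -> None:
        n = len(self.entity_ids)
        self.mfe = np.asarray(self.mfe, dtype=float)
        self.au_fraction = np.asarray(self.au_fraction, dtype=float)
        if self.mfe.shape != (n,) or self.au_fraction.shape != (n,):
            raise ValueError("feature arrays must have one entry per entity")
        if (self.mfe > 1e-9).any():
            raise ValueError("MFE values must be <= 0")
        if ((self.au_fraction < 0) | (self.au_fraction > 1)).any():
            raise ValueError("AU fractions must lie in [0, 1]")
        if self.accessibility is not None:
            self.accessibility = np.asarray(self.accessibility, dtype=float)
            if ((self.accessibility < 0) | (self.accessibility > 1)).any():
                raise ValueError("accessibility must lie in [0, 1]")

    def ssr_matrix(self, binary: bool = False) -> np.ndarray:
        M = self.ssr_counts.to_numpy(dtype=float)
        return (M > 0).astype(float) if binary else M

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"entity_id": self.entity_ids, "mfe": self.mfe,
                           "au_fraction": self.au_fraction})
        if self.accessibility is not None:
            df["accessibility"] = self.accessibility
        out = pd.concat([df, self.ssr_counts.reset_index(drop=True)], axis=1)
        out.to_csv(path, sep="\t", index=False)


def feature_table(ids: list[str], seqs: list[str],
                  provider: FoldingProvider | None = None,
                  with_accessibility: bool = False,
                  accessibility_window: int = 10,
                  min_repeats: int = 3) -> FeatureTable:
    """Compute the full feature table for one entity set."""
    provider = provider or NussinovProvider()
    mfe = np.array([compute_free_energy(s, provider) for s in seqs])
    au = np.array([compute_au_content(s) for s in seqs])
    per_seq = [extract_ssrs(s, min_repeats=min_repeats) for s in seqs]
    motifs = sorted({m for c in per_seq for m in c})
    ssr = pd.DataFrame(
        [[c.get(m, 0) for m in motifs] for c in per_seq],
        index=ids, columns=motifs, dtype=int,
    )
    acc = None
    if with_accessibility:
        acc = np.array([
            compute_accessibility(s, provider, min(accessibility_window, len(s)))
            for s in seqs
        ])
    return FeatureTable(list(ids), mfe, au, ssr, accessibility=acc,
                        provider_name=getattr(provider, "name", "custom"))
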