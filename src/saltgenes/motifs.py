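"""Promoter extraction, IUPAC consensus motif scanning and enrichment.

Promoters are fixed-length upstream flanks of the translation start site
(1,000 bp by default), strand-oriented at extraction time, so scanning is
forward-strand only. Motifs are IUPAC consensus strings matched exactly
(each degenerate letter is a set of concrete bases; ``N`` in a *sequence*
never matches). Target-versus-background presence is tested with a Pearson
chi-square on the 2x2 presence table (1 df, no continuity correction), and
candidate motifs are compared against reference motifs with a best-offset
ungapped match score: two motifs are called identical when the score exceeds
4 matched positions and more than 80% of the shorter motif's positions match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

__all__ = [
    "MotifConsensus",
    "PresenceTable",
    "extract_promoters",
    "scan_motif",
    "presence_table",
    "chi_square_presence",
    "compare_motifs",
]

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MotifConsensus:
    """A named IUPAC consensus motif (uppercase, nonempty)."""

    name: str
    iupac: str

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("empty motif")
        bad = set(self.iupac) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"invalid IUPAC letters in motif {self.name!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.iupac)


@dataclass(frozen=True)
class PresenceTable:
    """2x2 counts: rows (target, background) x columns (present, absent)."""

    target_present: int
    target_absent: int
    background_present: int
    background_absent: int

    def __post_init__(self) -> None:
        if min(
            self.target_present, self.target_absent,
            self.background_present, self.background_absent,
        ) < 0:
            raise ValueError("negative count")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                [self.target_present, self.target_absent],
                [self.background_present, self.background_absent],
            ]
        )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_promoters(
    genes: pd.DataFrame,
    genome: dict[str, str],
    length: int = 1000,
) -> dict[str, tuple[str, bool]]:
    """Upstream flanks of the translation start, strand-oriented.

    ``genes`` needs columns ``chrom, start, end, gene_id, strand`` (1-based
    inclusive). Plus strand takes bases ``[start-length, start-1]``; minus
    strand the reverse complement of ``[end+1, end+length]``. Returns
    ``gene_id -> (sequence, truncated_flag)``; flanks that run off a
    chromosome edge come back shorter with the flag set.
    """
    out: dict[str, tuple[str, bool]] = {}
    for row in genes.itertuples(index=False):
        chrom = str(row.chrom)
        if chrom not in genome:
            raise KeyError(f"chromosome {chrom!r} absent from genome for gene {row.gene_id}")
        seq = genome[chrom]
        if row.strand == "+":
            lo = max(1, int(row.start) - length)
            hi = int(row.start) - 1
            promoter = seq[lo - 1 : hi]
        else:
            lo = int(row.end) + 1
            hi = min(len(seq), int(row.end) + length)
            promoter = reverse_complement(seq[lo - 1 : hi])
        out[str(row.gene_id)] = (promoter, len(promoter) < length)
    return out


def _motif_regex(motif: MotifConsensus) -> re.Pattern[str]:
    # lookahead makes overlapping occurrences count; N excluded from classes
    # so an N in the scanned sequence never matches
    parts = ["[" + "".join(sorted(IUPAC_SETS[c])) + "]" for c in motif.iupac]
    return re.compile("(?=" + "".join(parts) + ")")


def scan_motif(
    sequences: dict[str, str], motif: MotifConsensus
) -> pd.DataFrame:
    """Count overlapping forward-strand IUPAC matches per sequence.

    Returns a DataFrame indexed by sequence id with ``n_occurrences`` and a
    boolean ``present`` flag. Sequences may contain A/C/G/T/N only.
    """
    pattern = _motif_regex(motif)
    rows = {}
    for name, seq in sequences.items():
        seq = seq.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence {name!r} contains non-ACGTN letters: {sorted(bad)}")
        n = len(pattern.findall(seq))
        rows[name] = {"n_occurrences": n, "present": n > 0}
    return pd.DataFrame.from_dict(rows, orient="index")


def presence_table(target_scan: pd.DataFrame, background_scan: pd.DataFrame) -> PresenceTable:
    """Collapse two scan tables into the 2x2 presence table."""
    tp = int(target_scan["present"].sum())
    bp = int(background_scan["present"].sum())
    return PresenceTable(
        target_present=tp,
        target_absent=len(target_scan) - tp,
        background_present=bp,
        background_absent=len(background_scan) - bp,
    )


def chi_square_presence(table: PresenceTable) -> tuple[float, float, bool]:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2 table.

    Returns ``(chi2, p, low_expected_warning)``; the flag is set when any
    expected cell is below 5. Zero marginals are an error.
    """
    arr = table.as_array()
    if arr.sum() == 0:
        raise ValueError("empty presence table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in presence table")
    chi2, p, _, expected = chi2_contingency(arr, correction=False)
    return float(chi2), float(p), bool((expected < 5).any())


def _position_matches(a: str, b: str) -> bool:
    sa, sb = IUPAC_SETS[a], IUPAC_SETS[b]
    if not sa & sb:
        return False
    return len(sa) == 1 or len(sb) == 1


def compare_motifs(a: MotifConsensus, b: MotifConsensus) -> tuple[int, float, bool]:
    """Best ungapped-offset match between two consensus motifs.

    A position matches when the two IUPAC sets intersect and at least one of
    the letters is unambiguous. ``score`` is the maximum number of matched
    positions over all offsets; ``matched_pct`` is score over the shorter
    motif's length (x100); the pair is called ``identical`` when score > 4
    and matched_pct > 80. Symmetric in its arguments.
    """
    x, y = a.iupac, b.iupac
    best = 0
    for offset in range(-(len(y) - 1), len(x)):
        matched = 0
        for i in range(len(x)):
            j = i - offset
            if 0 <= j < len(y) and _position_matches(x[i], y[j]):
                matched += 1
        best = max(best, matched)
    matched_pct = 100.0 * best / min(len(x), len(y))
    return best, matched_pct, bool(best > 4 and matched_pct > 80.0)
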