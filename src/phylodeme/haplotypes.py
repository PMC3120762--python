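"""Haplotype collapsing, diversity statistics and the parsimony connection limit.

An alignment (id -> equal-length sequence) plus a sample-to-deme map is
collapsed to a :class:`HaplotypeTable`: the distinct sequences with their
per-deme counts.  Diversity statistics operate on the table; alignment
columns containing symbols other than A/C/G/T (gaps, Ns) are excluded
from distance and site statistics, with the number of excluded columns
logged.

IUPAC heterozygote ambiguity codes are rejected outright: nuclear input
must arrive phased, with one record per allele copy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_AMBIGUITY = set("RYSWKMBDHV")
_VALID = set("ACGTN-")


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with per-deme counts.

    ``counts`` is a haplotype x deme DataFrame; haplotype ids are H1, H2,
    ... ordered by decreasing total count (ties by first occurrence in
    the alignment).  ``included_columns`` indexes the alignment columns
    used for distances and site statistics.
    """

    sequences: dict[str, str]            # haplotype id -> full sequence
    counts: pd.DataFrame                 # haplotypes x demes
    locus_length: int
    included_columns: np.ndarray
    members: dict[str, list[str]]        # haplotype id -> sample ids

    @property
    def haplotype_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def deme_labels(self) -> list[str]:
        return list(self.counts.columns)

    def n_per_deme(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def total_counts(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def core_sequence(self, hap_id: str) -> str:
        """The haplotype restricted to the included (clean) columns."""
        s = self.sequences[hap_id]
        return "".join(s[i] for i in self.included_columns)

    def distance_matrix(self) -> pd.DataFrame:
        """Pairwise Hamming distances over included columns."""
        ids = self.haplotype_ids
        arrs = [np.frombuffer(self.core_sequence(h).encode(), dtype=np.uint8) for h in ids]
        m = len(ids)
        D = np.zeros((m, m), dtype=int)
        for i in range(m):
            for j in range(i + 1, m):
                D[i, j] = D[j, i] = int((arrs[i] != arrs[j]).sum())
        return pd.DataFrame(D, index=ids, columns=ids)


def _validate_alignment(alignment: dict[str, str]) -> int:
    if not alignment:
        raise ValueError("empty alignment")
    lens = {len(s) for s in alignment.values()}
    if len(lens) != 1:
        raise ValueError(f"ragged alignment: sequence lengths {sorted(lens)}")
    for sid, seq in alignment.items():
        bad = set(seq.upper()) - _VALID
        amb = bad & _AMBIGUITY
        if amb:
            raise ValueError(
                f"sequence {sid!r} contains IUPAC ambiguity codes {sorted(amb)}; "
                "input must be phased/resolved (one record per allele copy)")
        if bad:
            raise ValueError(f"sequence {sid!r} contains invalid symbols {sorted(bad)}")
    return lens.pop()


def included_columns(alignment: dict[str, str]) -> np.ndarray:
    """Indices of columns consisting solely of A/C/G/T."""
    mat = np.vstack([np.frombuffer(s.upper().encode(), dtype=np.uint8) for s in alignment.values()])
    ok = np.ones(mat.shape[1], dtype=bool)
    for sym in "N-":
        ok &= ~(mat == ord(sym)).any(axis=0)
    return np.where(ok)[0]


def collapse_haplotypes(alignment: dict[str, str], deme_map: dict[str, str]) -> HaplotypeTable:
    """Group identical sequences (uppercased) and partition counts by deme."""
    L = _validate_alignment(alignment)
    missing = [sid for sid in alignment if sid not in deme_map]
    if missing:
        raise ValueError(f"sequence ids missing from deme map: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    demes = sorted(set(deme_map[sid] for sid in alignment))
    seq_to_members: dict[str, list[str]] = {}
    for sid in alignment:
        seq_to_members.setdefault(alignment[sid].upper(), []).append(sid)
    ordered = sorted(seq_to_members, key=lambda s: (-len(seq_to_members[s]),
                                                    min(list(alignment).index(m) for m in seq_to_members[s])))
    hap_ids = [f"H{i + 1}" for i in range(len(ordered))]
    counts = pd.DataFrame(0, index=hap_ids, columns=demes)
    sequences, members = {}, {}
    for hid, seq in zip(hap_ids, ordered):
        sequences[hid] = seq
        members[hid] = seq_to_members[seq]
        for sid in seq_to_members[seq]:
            counts.loc[hid, deme_map[sid]] += 1
    cols = included_columns(alignment)
    n_excl = L - len(cols)
    if n_excl:
        logger.info("excluding %d alignment column(s) containing non-ACGT symbols", n_excl)
    return HaplotypeTable(sequences, counts, L, cols, members)


def haplotype_diversity(counts) -> float:
    """Nei's unbiased haplotype diversity h = n/(n-1) (1 - sum p_i^2)."""
    c = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts, dtype=float)
    c = c[c > 0]
    n = c.sum()
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2 sequences")
    p = c / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p ** 2)))


def nucleotide_diversity(table: HaplotypeTable, deme: str | None = None) -> float:
    """Mean pairwise difference per site, over all pairs without replacement.

    With ``deme`` given, restricted to that deme's sequences.  The
    denominator is the number of included (clean) columns.
    """
    counts = table.counts[deme] if deme is not None else table.total_counts()
    c = counts.to_numpy(dtype=float)
    n = c.sum()
    if n < 2:
        raise ValueError("nucleotide diversity requires n >= 2 sequences")
    L_used = len(table.included_columns)
    if L_used == 0:
        raise ValueError("no clean alignment columns available")
    D = table.distance_matrix().to_numpy()
    num = 0.0
    for i in range(len(c)):
        for j in range(i + 1, len(c)):
            num += c[i] * c[j] * D[i, j]
    return float(num / (n * (n - 1) / 2.0) / L_used)


def classify_segregating_sites(alignment: dict[str, str]) -> tuple[int, int]:
    """(singleton mutation count, parsimony-informative site count).

    A variable column is parsimony-informative iff at least two bases
    each occur in at least two sequences.  In a non-PI variable column,
    every base carried by exactly one sequence counts as one singleton
    mutation; a column split between two unique bases (n = 2) counts one.
    """
    _validate_alignment(alignment)
    if len(alignment) < 2:
        raise ValueError("site classification requires >= 2 sequences")
    mat = np.vstack([np.frombuffer(s.upper().encode(), dtype=np.uint8) for s in alignment.values()])
    cols = included_columns(alignment)
    n_singleton = 0
    n_pi = 0
    for j in cols:
        vals, cnts = np.unique(mat[:, j], return_counts=True)
        if len(vals) < 2:
            continue
        if (cnts >= 2).sum() >= 2:
            n_pi += 1
        else:
            ones = int((cnts == 1).sum())
            n_singleton += ones if cnts.max() >= 2 else ones - 1
    return n_singleton, n_pi


def parsimony_probability(j: int, L: int) -> float:
    """Probability that j mutations on an L-site sequence are all at
    distinct sites, so that the j-step connection is parsimonious.

    Under uniform placement of mutation events across sites, a repeated
    hit always shortens the observable path (either a back mutation or a
    two-step change at one site), so the probability of parsimony for a
    j-step connection is the no-repeat probability
    ``prod_{i=1}^{j-1} (1 - i/L)``.
    """
    if j <= 1:
        return 1.0
    if j > L:
        return 0.0
    i = np.arange(1, j)
    return float(np.prod(1.0 - i / L))


def connection_limit(L: int, confidence: float = 0.95) -> int:
    """Largest step count whose probability of parsimony is >= confidence.

    Capped at L (the documented maximum: more steps than sites can never
    be parsimonious).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    j = 1
    while j < L and parsimony_probability(j + 1, L) >= confidence:
        j += 1
    return j
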