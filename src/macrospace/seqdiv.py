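"""Sequence-divergence analytics for pairwise-aligned regions.

Two layers:

* **Genomic windows** — per-base mismatch density between two aligned
  sequences in sliding windows (default 100 bases, step 25), optionally
  corrected by subtracting a genome-wide background rate estimated from a
  pooled set of aligned background regions (e.g. three 20-kb regions).

* **Coding regions** — codon-level classification of nucleotide differences
  into amino-acid-changing versus silent, using Nei–Gojobori (1986) equal
  pathway averaging; synonymous/nonsynonymous site counting; Jukes–Cantor
  corrected Ka and Ks; and a Pearson chi-squared contingency test comparing
  the substitution-class composition across genes.

Alignment conventions: sequences are compared column by column on the
alignment; positions where either sequence has a gap or an ambiguous base
(anything outside ACGT) are masked and removed from both the mismatch count
and the denominator.  Codons containing masked columns are skipped.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "WindowParams",
    "SubstitutionCounts",
    "ContingencyResult",
    "window_snp_density",
    "background_rate",
    "background_correct",
    "classify_substitutions",
    "ka_ks",
    "analyze_coding_pair",
    "substitution_contingency",
    "read_fasta_pair",
    "write_substitution_table",
    "CODON_TO_AA",
    "STOP_CODONS",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_TABLE.forward_table)
STOP_CODONS = frozenset(_TABLE.stop_codons)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"
_BASES = "ACGT"


@dataclass(frozen=True)
class WindowParams:
    """Sliding-window geometry: window size w and step s, in alignment bases."""

    window: int = 100
    step: int = 25

    def __post_init__(self):
        if not self.window >= self.step > 0:
            raise ValueError("need window >= step > 0")


# ---------------------------------------------------------------------------
# windowed mismatch density


def _encode_pair(seq_a: str, seq_b: str):
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    if a.size != b.size:
        raise ValueError("aligned sequences must have equal length")
    acgt = np.frombuffer(b"ACGT", dtype="S1")
    valid = np.isin(a, acgt) & np.isin(b, acgt)
    diff = valid & (a != b)
    return diff, valid


def window_snp_density(seq_a: str, seq_b: str,
                       params: WindowParams = WindowParams()) -> pd.DataFrame:
    """Mismatch density in sliding windows along a pairwise alignment.

    Windows start at 0, s, 2s, ... while ``start + w`` fits in the alignment
    (partial terminal windows are discarded).  Density is mismatches over
    the window's unmasked columns; fully masked windows get NaN.
    Returns start, end, n_diff, n_valid, density.
    """
    diff, valid = _encode_pair(seq_a, seq_b)
    w, s = params.window, params.step
    if diff.size < w:
        raise ValueError("alignment shorter than one window")
    cdiff = np.concatenate([[0], np.cumsum(diff)])
    cvalid = np.concatenate([[0], np.cumsum(valid)])
    starts = np.arange(0, diff.size - w + 1, s)
    n_diff = cdiff[starts + w] - cdiff[starts]
    n_valid = cvalid[starts + w] - cvalid[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(n_valid > 0, n_diff / np.maximum(n_valid, 1), np.nan)
    return pd.DataFrame(
        {
            "start": starts,
            "end": starts + w,
            "n_diff": n_diff,
            "n_valid": n_valid,
            "density": density,
        }
    )


def background_rate(background_pairs) -> float:
    """Pooled per-base difference frequency over aligned background regions:
    total differences / total comparable bases (ratio of sums)."""
    total_diff = 0
    total_valid = 0
    for seq_a, seq_b in background_pairs:
        diff, valid = _encode_pair(seq_a, seq_b)
        total_diff += int(diff.sum())
        total_valid += int(valid.sum())
    if total_valid == 0:
        raise ValueError("background regions contain no comparable bases")
    return total_diff / total_valid


def background_correct(track: pd.DataFrame, background_pairs) -> pd.DataFrame:
    """Subtract the pooled background rate from every window's density.

    Corrected values may be negative — the background is a noise estimate,
    not a floor.  Returns a copy with columns background and corrected.
    """
    rate = background_rate(background_pairs)
    out = track.copy()
    out["background"] = rate
    out["corrected"] = out["density"] - rate
    return out


# ---------------------------------------------------------------------------
# codon-level classification (Nei-Gojobori pathway averaging)


@dataclass
class SubstitutionCounts:
    """Substitution tallies and rates for one coding-region alignment.

    ``n_nonsyn``/``n_syn`` are pathway-averaged fractional counts;
    ``nonsyn_int``/``syn_int`` round them half-away-from-zero for table
    display.  ``nonsyn_sites`` (N) and ``syn_sites`` (S) satisfy
    N + S = 3 x compared codons.  Rates are filled by :func:`ka_ks`.
    """

    gene_id: str = ""
    n_nonsyn: float = 0.0
    n_syn: float = 0.0
    nonsyn_sites: float = 0.0
    syn_sites: float = 0.0
    n_codons: int = 0
    n_flagged_codons: int = 0  # codon pairs whose every pathway crosses a stop
    pn: float = float("nan")
    ps: float = float("nan")
    ka: float = float("nan")
    ks: float = float("nan")
    ka_ks: float = float("nan")
    ka_ks_defined: bool = False

    @property
    def nonsyn_int(self) -> int:
        return int(np.floor(self.n_nonsyn + 0.5))

    @property
    def syn_int(self) -> int:
        return int(np.floor(self.n_syn + 0.5))


def _codon_sites(codon: str):
    """(nonsynonymous, synonymous) site counts of one sense codon.

    Per position, each of the three possible point mutations is classified;
    mutations to stop codons count as nonsynonymous (amino-acid-changing in
    the broad sense).  Site fractions sum to 3 per codon.
    """
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1:]
            if CODON_TO_AA[mutant] == aa:
                syn += 1.0 / 3.0
    return 3.0 - syn, syn


_SITES_CACHE = {c: _codon_sites(c) for c in CODON_TO_AA if c not in STOP_CODONS}


def _pathway_counts(codon_a: str, codon_b: str):
    """Pathway-averaged (nonsyn, syn, flagged) differences between two codons.

    All orderings of the differing positions are enumerated; each ordering
    is a chain of single-nucleotide steps whose amino-acid effect is
    classified step by step.  Orderings whose intermediate codons are stops
    are excluded; if every ordering is excluded the pair is averaged over
    all orderings anyway and flagged.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0, False

    def walk(order):
        steps = []
        cur = codon_a
        for i in order:
            nxt = cur[:i] + codon_b[i] + cur[i + 1:]
            steps.append((cur, nxt))
            cur = nxt
        # intermediates are every codon after a step except the final one
        if any(CODON_TO_AA[nxt] == "*" for _, nxt in steps[:-1]):
            return None
        n = s = 0.0
        for c1, c2 in steps:
            if CODON_TO_AA[c1] == CODON_TO_AA[c2]:
                s += 1.0
            else:
                n += 1.0
        return n, s

    paths = [walk(order) for order in itertools.permutations(diff_pos)]
    usable = [p for p in paths if p is not None]
    flagged = not usable
    if flagged:  # fall back to minimum-change over all orderings
        usable = [walk_all for order in itertools.permutations(diff_pos)
                  for walk_all in [_walk_through_stops(codon_a, codon_b, order)]]
    n = float(np.mean([p[0] for p in usable]))
    s = float(np.mean([p[1] for p in usable]))
    return n, s, flagged


def _walk_through_stops(codon_a, codon_b, order):
    n = s = 0.0
    cur = codon_a
    for i in order:
        nxt = cur[:i] + codon_b[i] + cur[i + 1:]
        if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
            s += 1.0
        else:
            n += 1.0
        cur = nxt
    return n, s


_PATHWAY_CACHE: dict = {}


def classify_substitutions(seq_a: str, seq_b: str, gene_id: str = "",
                           frame: int = 0) -> SubstitutionCounts:
    """Classify codon-level differences between two aligned coding sequences.

    Starting at ``frame``, the alignment is read codon by codon; codons
    containing a gap or ambiguous base in either sequence are skipped.
    Differences per codon pair are split into amino-acid-changing and
    silent by Nei–Gojobori equal pathway averaging, and synonymous /
    nonsynonymous site totals are averaged over the two sequences.
    Premature (internal) stop codons are a frame violation and raise.
    """
    a = seq_a.upper()
    b = seq_b.upper()
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    counts = SubstitutionCounts(gene_id=gene_id)
    usable = len(a) - frame
    n_codon_cols = usable // 3
    sites_a = sites_b = 0.0
    for k in range(n_codon_cols):
        i = frame + 3 * k
        ca, cb = a[i:i + 3], b[i:i + 3]
        if any(ch not in _BASES for ch in ca + cb):
            continue
        last_codon = k == n_codon_cols - 1
        for c in (ca, cb):
            if c in STOP_CODONS and not last_codon:
                raise ValueError(f"internal stop codon {c} at alignment column {i}")
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue  # aligned terminal stops carry no site information
        key = (ca, cb)
        if key not in _PATHWAY_CACHE:
            _PATHWAY_CACHE[key] = _pathway_counts(ca, cb)
        n, s, flagged = _PATHWAY_CACHE[key]
        counts.n_nonsyn += n
        counts.n_syn += s
        counts.n_flagged_codons += flagged
        counts.n_codons += 1
        na, sa = _SITES_CACHE[ca]
        nb, sb = _SITES_CACHE[cb]
        sites_a += sa
        sites_b += sb
    counts.syn_sites = (sites_a + sites_b) / 2.0
    counts.nonsyn_sites = 3.0 * counts.n_codons - counts.syn_sites
    return counts


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def ka_ks(counts: SubstitutionCounts) -> SubstitutionCounts:
    """Fill per-site rates: pN, pS and Jukes–Cantor corrected Ka, Ks.

    ``Ka = -(3/4) ln(1 - 4 pN / 3)`` with ``pN = n_nonsyn / N`` (likewise
    Ks).  The ratio is flagged undefined when Ks = 0; proportions >= 3/4
    leave the corrected rate NaN.  Returns the same object, updated.
    """
    if counts.nonsyn_sites <= 0 or counts.syn_sites <= 0:
        raise ValueError("need positive nonsynonymous and synonymous site totals")
    counts.pn = counts.n_nonsyn / counts.nonsyn_sites
    counts.ps = counts.n_syn / counts.syn_sites
    if counts.pn >= 0.75 or counts.ps >= 0.75:
        warnings.warn("difference proportion >= 3/4: Jukes-Cantor correction undefined",
                      stacklevel=2)
    counts.ka = _jukes_cantor(counts.pn)
    counts.ks = _jukes_cantor(counts.ps)
    if counts.ks and np.isfinite(counts.ks):
        counts.ka_ks = counts.ka / counts.ks
        counts.ka_ks_defined = np.isfinite(counts.ka_ks)
    else:
        counts.ka_ks = float("nan")
        counts.ka_ks_defined = False
    return counts


def analyze_coding_pair(seq_a: str, seq_b: str, gene_id: str = "",
                        frame: int = 0) -> SubstitutionCounts:
    """Convenience: classify substitutions then fill Ka/Ks."""
    return ka_ks(classify_substitutions(seq_a, seq_b, gene_id=gene_id, frame=frame))


# ---------------------------------------------------------------------------
# contingency test across genes


@dataclass(frozen=True)
class ContingencyResult:
    chi2: float
    df: int
    p_value: float
    expected_below_5: bool


def substitution_contingency(genes) -> ContingencyResult:
    """Pearson chi-squared on the genes x {AA-changing, silent} table.

    Tests whether the split of nucleotide differences into amino-acid-
    changing versus silent is homogeneous across genes; df = genes - 1.
    Uses the rounded integer counts.  Emits a warning when any expected
    count falls below 5 (the chi-squared approximation is then shaky).
    """
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    table = np.array([[g.nonsyn_int, g.syn_int] for g in genes], dtype=float)
    if table.sum() == 0:
        raise ValueError("all-zero contingency table")
    chi2, p, df, expected = scipy.stats.chi2_contingency(table, correction=False)
    low = bool((expected < 5).any())
    if low:
        warnings.warn("expected count < 5 in contingency table", stacklevel=2)
    return ContingencyResult(chi2=float(chi2), df=int(df), p_value=float(p),
                             expected_below_5=low)


# ---------------------------------------------------------------------------
# I/O


def read_fasta_pair(path):
    """The two records of a pairwise-aligned FASTA, as (id, seq) tuples."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"expected exactly 2 aligned records, found {len(records)}")
    a, b = records
    if len(a.seq) != len(b.seq):
        raise ValueError("aligned records have unequal lengths")
    return (a.id, str(a.seq)), (b.id, str(b.seq))


def write_substitution_table(genes, path) -> None:
    """TSV with one row per gene: AA-changing, silent (integer and
    fractional) and Ka/Ks."""
    rows = []
    for g in genes:
        rows.append(
            {
                "gene": g.gene_id,
                "aa_changing": g.nonsyn_int,
                "silent": g.syn_int,
                "aa_changing_frac": round(g.n_nonsyn, 4),
                "silent_frac": round(g.n_syn, 4),
                "ka": round(g.ka, 4) if np.isfinite(g.ka) else "NA",
                "ks": round(g.ks, 4) if np.isfinite(g.ks) else "NA",
                "ka_ks": round(g.ka_ks, 4) if g.ka_ks_defined else "NA",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
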