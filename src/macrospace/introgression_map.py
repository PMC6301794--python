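"""Introgression-region mapping from pooled donor-allele frequencies.

Given genotype tables for two parental species, species-diagnostic SNPs are
the sites fixed for different alleles in the two species (within-species
polymorphic sites are excluded).  Pooled sequencing of an introgressed line
then yields, per diagnostic SNP, a depth and a donor-allele read count; the
donor frequency, windowed along each chromosome, localises the retained
donor regions.  Regions are segmented as runs of windows above a frequency
threshold and annotated against gene models.

Windowing defaults (window 100 kb, non-overlapping, >= 5 SNPs/window) and
the 0.25 detection threshold reflect that a heterozygous introgressed
segment in a pooled sample sits at an expected donor frequency of 0.5, so
0.25 separates signal from the ~0 background.

Coordinates: 0-based half-open internally and in BED/bedGraph output;
1-based in SNP/pool TSV and VCF I/O.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "call_diagnostic_snps",
    "donor_frequency_windows",
    "detect_regions",
    "annotate_regions",
    "read_gene_intervals",
    "write_bedgraph",
    "write_regions_bed",
    "write_snps_vcf",
]

_BASES = ["A", "C", "G", "T"]


def _fixed_allele(row, min_count: int):
    """The single observed allele of a site, or None if polymorphic or
    observed fewer than min_count times."""
    counts = [(b, row[b]) for b in _BASES if row[b] > 0]
    if len(counts) != 1:
        return None
    base, n = counts[0]
    return base if n >= min_count else None


def call_diagnostic_snps(donor_table: pd.DataFrame, recipient_table: pd.DataFrame,
                         min_count: int = 5) -> pd.DataFrame:
    """Species-diagnostic SNPs: sites fixed for different alleles.

    Both tables need columns chrom, pos (1-based) and per-base allele counts
    A, C, G, T over the sampled chromosomes of that species.  A site is
    diagnostic when each species shows exactly one allele, with at least
    ``min_count`` observations, and the two alleles differ.  Sites
    polymorphic within either species are excluded.

    Returns a sorted table chrom, pos, donor_allele, recipient_allele.
    """
    merged = donor_table.merge(
        recipient_table, on=["chrom", "pos"], suffixes=("_d", "_r"), how="inner"
    )
    if len(merged) == 0:
        raise ValueError("parental tables share no sites")
    rows = []
    for row in merged.itertuples(index=False):
        d = _fixed_allele({b: getattr(row, f"{b}_d") for b in _BASES}, min_count)
        r = _fixed_allele({b: getattr(row, f"{b}_r") for b in _BASES}, min_count)
        if d is not None and r is not None and d != r:
            rows.append((row.chrom, row.pos, d, r))
    out = pd.DataFrame(rows, columns=["chrom", "pos", "donor_allele", "recipient_allele"])
    return out.sort_values(["chrom", "pos"], ignore_index=True)


def donor_frequency_windows(snps: pd.DataFrame, counts: pd.DataFrame,
                            window_bp: int = 100_000, step_bp: int = 100_000,
                            min_snps: int = 5, chrom_lengths: dict = None) -> pd.DataFrame:
    """Windowed donor-allele frequency along each chromosome.

    Per window the frequency is the ratio of sums — total donor reads over
    total depth across the SNPs inside — which is robust to uneven depth.
    Windows with fewer than ``min_snps`` covered SNPs (or zero depth) get
    NaN.  ``counts`` must cover the SNP table (merged on chrom, pos).
    Window span defaults to the last SNP position; pass ``chrom_lengths``
    to tile whole chromosomes.
    """
    if window_bp < step_bp or step_bp <= 0:
        raise ValueError("need window_bp >= step_bp > 0")
    if len(snps) == 0:
        raise ValueError("empty diagnostic SNP set")
    merged = snps.merge(counts, on=["chrom", "pos"], how="left")
    if merged["depth"].isna().any():
        raise ValueError("pool counts do not cover the diagnostic SNP table")
    out = []
    for chrom, group in merged.groupby("chrom", sort=True):
        group = group.sort_values("pos")
        pos0 = group["pos"].to_numpy(np.int64) - 1
        depth = group["depth"].to_numpy(np.int64)
        reads = group["donor_reads"].to_numpy(np.int64)
        cdepth = np.concatenate([[0], np.cumsum(depth)])
        creads = np.concatenate([[0], np.cumsum(reads)])
        span = chrom_lengths[chrom] if chrom_lengths else int(pos0[-1]) + 1
        starts = np.arange(0, max(span - window_bp, 0) + 1, step_bp, dtype=np.int64)
        if len(starts) == 0:
            starts = np.array([0], dtype=np.int64)
        ends = np.minimum(starts + window_bp, span)
        lo = np.searchsorted(pos0, starts, side="left")
        hi = np.searchsorted(pos0, ends, side="left")
        n_snps = hi - lo
        wdepth = cdepth[hi] - cdepth[lo]
        wreads = creads[hi] - creads[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(wdepth > 0, wreads / np.maximum(wdepth, 1), np.nan)
        freq = np.where(n_snps >= min_snps, freq, np.nan)
        out.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "freq": freq,
                    "n_snps": n_snps,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def detect_regions(track: pd.DataFrame, threshold: float = 0.25,
                   min_windows: int = 3, max_gap_windows: int = 1) -> pd.DataFrame:
    """Segment introgressed regions from a windowed frequency track.

    A region is a maximal run of windows with frequency >= ``threshold``,
    allowing up to ``max_gap_windows`` consecutive sub-threshold or missing
    windows inside, and is kept when it contains at least ``min_windows``
    above-threshold windows.  Region bounds run from the first to the last
    above-threshold window.  Returns chrom, start, end, mean_freq (mean over
    the above-threshold windows), n_windows.
    """
    regions = []
    for chrom, group in track.groupby("chrom", sort=True):
        group = group.sort_values("start").reset_index(drop=True)
        hit = (group["freq"].to_numpy() >= threshold) & group["freq"].notna().to_numpy()
        idx = np.nonzero(hit)[0]
        if len(idx) == 0:
            continue
        runs = [[idx[0]]]
        for i in idx[1:]:
            if i - runs[-1][-1] - 1 <= max_gap_windows:
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            if len(run) < min_windows:
                continue
            first, last = run[0], run[-1]
            regions.append(
                {
                    "chrom": chrom,
                    "start": int(group.loc[first, "start"]),
                    "end": int(group.loc[last, "end"]),
                    "mean_freq": float(group.loc[run, "freq"].mean()),
                    "n_windows": len(run),
                }
            )
    return pd.DataFrame(regions, columns=["chrom", "start", "end", "mean_freq", "n_windows"])


def annotate_regions(regions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Overlap regions with gene intervals (any >= 1 bp overlap counts).

    ``genes`` needs columns chrom, start, end (0-based half-open), gene_id.
    Regions on chromosomes absent from the annotation are warned about and
    reported with zero genes.  Adds n_genes and a comma-joined gene list.
    """
    if (genes["end"] <= genes["start"]).any():
        raise ValueError("invalid gene intervals (end <= start)")
    trees = {}
    for chrom, group in genes.groupby("chrom"):
        tree = IntervalTree()
        for row in group.itertuples(index=False):
            tree.addi(row.start, row.end, row.gene_id)
        trees[chrom] = tree
    out = regions.copy()
    n_genes, gene_lists = [], []
    for row in regions.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            warnings.warn(f"chromosome {row.chrom!r} absent from annotation; skipped",
                          stacklevel=2)
            hits = []
        else:
            hits = sorted({iv.data for iv in tree.overlap(row.start, row.end)})
        n_genes.append(len(hits))
        gene_lists.append(",".join(hits))
    out["n_genes"] = n_genes
    out["genes"] = gene_lists
    return out


def read_gene_intervals(path) -> pd.DataFrame:
    """Gene intervals from GFF3 (``gene`` features) or BED6.

    Returns chrom, start, end (0-based half-open), gene_id.  GFF3 is parsed
    with pyranges; gene identifiers come from ID, then Name, then gene_id
    attributes.  BED files are taken as already 0-based half-open.
    """
    import pyranges as pr

    path = str(path)
    if path.endswith((".gff", ".gff3")):
        df = pr.read_gff3(path).df
        df = df[df["Feature"] == "gene"]
        for attr in ("ID", "Name", "gene_id"):
            if attr in df.columns and df[attr].notna().all():
                ids = df[attr]
                break
        else:
            raise ValueError("GFF3 gene features lack ID/Name/gene_id attributes")
        out = pd.DataFrame(
            {
                "chrom": df["Chromosome"].astype(str),
                "start": df["Start"].astype(np.int64),
                "end": df["End"].astype(np.int64),
                "gene_id": ids.astype(str),
            }
        )
    elif path.endswith(".bed"):
        bed = pd.read_csv(path, sep="\t", header=None, comment="#")
        out = pd.DataFrame(
            {
                "chrom": bed[0].astype(str),
                "start": bed[1].astype(np.int64),
                "end": bed[2].astype(np.int64),
                "gene_id": bed[3].astype(str) if bed.shape[1] > 3
                else bed.index.astype(str),
            }
        )
    else:
        raise ValueError(f"unrecognised annotation format: {path}")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# writers


def write_bedgraph(track: pd.DataFrame, path, value_col: str = "freq") -> None:
    """Windowed track as bedGraph (0-based half-open); missing windows skipped."""
    rows = track.dropna(subset=[value_col])
    with open(path, "w") as fh:
        for row in rows.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{getattr(row, value_col):.6g}\n")


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    """Regions as BED5 with score = mean donor frequency."""
    with open(path, "w") as fh:
        for i, row in enumerate(regions.itertuples(index=False)):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\tregion{i + 1}\t{row.mean_freq:.4f}\n"
            )


def write_snps_vcf(snps: pd.DataFrame, path, donor_freq: pd.Series = None) -> None:
    """Minimal VCF v4.2 of diagnostic SNPs (REF = recipient, ALT = donor)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Donor allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, row in enumerate(snps.itertuples(index=False)):
            info = f"AF={donor_freq.iloc[i]:.4f}" if donor_freq is not None else "."
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.recipient_allele}\t"
                f"{row.donor_allele}\t.\tPASS\t{info}\n"
            )
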