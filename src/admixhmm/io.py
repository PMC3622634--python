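"""Readers and writers for the formats the pipeline touches.

Plain-text VCF (phased haplotypes or genotype dosages, read via cyvcf2),
HapMap-dialect genetic maps, read-count TSVs, truth tracks, segmentation
tables, per-SNP ancestry calls with a BED-like collapsed segment form, and
JSON metric reports. SNP coordinates are 1-based in VCF/TSV and 0-based
half-open in BED, as those formats require; population and haplotype
indices are serialized 1-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genmap import GeneticMap


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

def read_genetic_map(path) -> GeneticMap:
    """Read a genetic map in the HapMap 3-column dialect or a 2-column one.

    3 columns: position, rate (cM/Mb, ignored), cumulative cM. 2 columns:
    position, cumulative cM. A header line is detected and skipped.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     skip_blank_lines=True)
    if not str(df.iloc[0, 0]).lstrip("-").replace(".", "", 1).isdigit():
        df = df.iloc[1:].reset_index(drop=True)
    df = df.astype(float)
    if df.shape[1] >= 3:
        return GeneticMap(positions=df.iloc[:, 0].to_numpy(),
                          cm=df.iloc[:, 2].to_numpy())
    if df.shape[1] == 2:
        return GeneticMap(positions=df.iloc[:, 0].to_numpy(),
                          cm=df.iloc[:, 1].to_numpy())
    raise ValueError("genetic map needs 2 or 3 columns")


def write_genetic_map(gmap: GeneticMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tcM\n")
        for p, c in zip(gmap.positions, gmap.cm):
            fh.write(f"{p:.0f}\t{c:.8g}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(path, haplotypes: np.ndarray, positions, chrom: str = "1",
              sample_names=None, phased: bool = True) -> None:
    """Write a biallelic SNP VCF with (un)phased GT fields.

    ``haplotypes`` is (2N, L) binary; consecutive chain pairs form one
    sample. Alleles are written REF=A, ALT=T as placeholders.
    """
    H = np.asarray(haplotypes)
    n_chains, L = H.shape
    n_samp = n_chains // 2
    if sample_names is None:
        sample_names = [f"sample{i + 1}" for i in range(n_samp)]
    sep = "|" if phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        for j in range(L):
            fields = [f"{int(H[2 * i, j])}{sep}{int(H[2 * i + 1, j])}"
                      for i in range(n_samp)]
            fh.write(f"{chrom}\t{int(positions[j])}\tsnp{j + 1}\tA\tT\t.\tPASS\t.\tGT\t"
                     + "\t".join(fields) + "\n")


def read_vcf_phased(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read phased haplotypes from a VCF.

    Returns the (2N, L) binary haplotype matrix, SNP positions (bp) and the
    sample names. Multi-allelic sites are skipped with a warning; missing
    or unphased genotypes are an error in haplotype mode.
    """
    from cyvcf2 import VCF
    import warnings

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, positions = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(f"skipping multi-allelic site at {var.POS}")
            continue
        col = []
        for g in var.genotypes:  # [a0, a1, phased]
            if g[0] < 0 or g[1] < 0:
                raise ValueError(f"missing genotype at position {var.POS}")
            if not g[2]:
                raise ValueError(f"unphased genotype at position {var.POS}")
            col.extend([g[0], g[1]])
        rows.append(col)
        positions.append(var.POS)
    vcf.close()
    if not rows:
        raise ValueError("no usable biallelic records in VCF")
    H = np.array(rows, dtype=np.int8).T
    return H, np.array(positions, dtype=float), samples


def read_vcf_genotypes(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read genotype dosages (0/1/2) from a VCF; phasing is not required."""
    from cyvcf2 import VCF
    import warnings

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, positions = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(f"skipping multi-allelic site at {var.POS}")
            continue
        col = []
        for g in var.genotypes:
            if g[0] < 0 or g[1] < 0:
                raise ValueError(f"missing genotype at position {var.POS}")
            col.append(g[0] + g[1])
        rows.append(col)
        positions.append(var.POS)
    vcf.close()
    G = np.array(rows, dtype=np.int8).T
    return G, np.array(positions, dtype=float), samples


# ---------------------------------------------------------------------------
# read counts
# ---------------------------------------------------------------------------

def write_read_counts(path, counts: np.ndarray, positions,
                      sample_names=None) -> None:
    """TSV: snp_id, pos, then refCount/altCount column pairs per individual."""
    counts = np.asarray(counts)
    N, L, _ = counts.shape
    if sample_names is None:
        sample_names = [f"sample{i + 1}" for i in range(N)]
    cols = {"snp_id": [f"snp{j + 1}" for j in range(L)],
            "pos": [int(p) for p in positions]}
    for i, name in enumerate(sample_names):
        cols[f"{name}.refCount"] = counts[i, :, 0]
        cols[f"{name}.altCount"] = counts[i, :, 1]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_read_counts(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    positions = df["pos"].to_numpy(dtype=float)
    ref_cols = [c for c in df.columns if c.endswith(".refCount")]
    names = [c[: -len(".refCount")] for c in ref_cols]
    counts = np.stack(
        [np.stack([df[f"{n}.refCount"].to_numpy(),
                   df[f"{n}.altCount"].to_numpy()], axis=-1) for n in names]
    )
    return counts.astype(np.int64), positions, names


# ---------------------------------------------------------------------------
# ancestry / truth tracks
# ---------------------------------------------------------------------------

def write_ancestry_tsv(path, labels: np.ndarray, positions, chrom: str = "1",
                       label_freq: np.ndarray | None = None,
                       header_lines: list[str] | None = None) -> None:
    """Per-SNP TSV: chrom, pos, individual, hap (1|2), label, [posteriors]."""
    labels = np.asarray(labels)
    n_chains, L = labels.shape
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        cols = "chrom\tpos\tindividual\thap\tlabel"
        if label_freq is not None:
            cols += "\t" + "\t".join(f"p{q + 1}" for q in range(label_freq.shape[2]))
        fh.write(cols + "\n")
        for c in range(n_chains):
            i, l = c // 2 + 1, c % 2 + 1
            for j in range(L):
                row = f"{chrom}\t{int(positions[j])}\t{i}\t{l}\t{labels[c, j] + 1}"
                if label_freq is not None:
                    row += "\t" + "\t".join(f"{p:.4g}" for p in label_freq[c, j])
                fh.write(row + "\n")


def write_ancestry_bed(path, labels: np.ndarray, positions,
                       chrom: str = "1") -> None:
    """BED-like collapsed segments (0-based half-open) per haplotype.

    Each maximal constant-label run becomes one interval; interval bounds
    are the positions of the first SNP of the run and of the first SNP of
    the next run (or one past the final SNP).
    """
    labels = np.asarray(labels)
    n_chains, L = labels.shape
    pos = np.asarray(positions)
    ends = np.append(pos[1:], pos[-1] + 1)
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tindividual\thap\tlabel\n")
        for c in range(n_chains):
            i, l = c // 2 + 1, c % 2 + 1
            run_start = 0
            for j in range(1, L + 1):
                if j == L or labels[c, j] != labels[c, run_start]:
                    fh.write(f"{chrom}\t{int(pos[run_start])}\t{int(ends[j - 1])}\t"
                             f"{i}\t{l}\t{labels[c, run_start] + 1}\n")
                    run_start = j


def read_ancestry_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", comment="#")
    n_chains = df[["individual", "hap"]].drop_duplicates().shape[0]
    positions = np.sort(df["pos"].unique()).astype(float)
    L = positions.size
    labels = np.empty((n_chains, L), dtype=np.int64)
    pos_idx = {p: j for j, p in enumerate(positions)}
    for _, row in df.iterrows():
        c = (int(row["individual"]) - 1) * 2 + int(row["hap"]) - 1
        labels[c, pos_idx[row["pos"]]] = int(row["label"]) - 1
    return labels, positions


write_truth_track = write_ancestry_tsv  # same schema (truth labels)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def write_segments(path, segs, states: np.ndarray) -> None:
    """Segmentation TSV: individual, hap, a, b (1-based inclusive), state."""
    with open(path, "w") as fh:
        fh.write("individual\thap\ta\tb\tstate\n")
        for c in range(segs.n_chains):
            i, l = c // 2 + 1, c % 2 + 1
            for a, b in segs.segments(c):
                fh.write(f"{i}\t{l}\t{a + 1}\t{b + 1}\t{states[c, a] + 1}\n")


def write_recomb_probs(path, r: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("snp\tr\n")
        for j, rj in enumerate(r):
            fh.write(f"{j + 1}\t{rj:.6g}\n")


def write_metrics_json(path, metrics: dict) -> None:
    def _clean(x):
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, dict):
            return {k: _clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [_clean(v) for v in x]
        return x

    Path(path).write_text(json.dumps(_clean(metrics), indent=2) + "\n")


def read_ref_labels(path, sample_names: list[str]) -> np.ndarray:
    """2-column TSV (sample_id, population_label 1-based) -> per-individual
    label array with -1 for unlisted (sample) individuals."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "pop"],
                     comment="#", dtype={"sample": str})
    lut = dict(zip(df["sample"], df["pop"].astype(int) - 1))
    return np.array([lut.get(s, -1) for s in sample_names], dtype=np.int64)
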