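"""Readers and writers for the pipeline's on-disk formats.

VCF carries SNV/indel genotypes (GT:DP:GQ per sample, 1-based positions);
BED files carry annotation tracks (0-based half-open); SVs travel in a
BEDPE-style TSV (chrom, start, end, svtype, population overlap, per-sample
genotypes); phenotype/covariates, per-sample count matrices and truth
records are plain TSV.  Coordinate conversion happens only here.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import CohortGenotypes, SVCallSet

_GT_CODE = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
_GT_PARSE = {"./.": -1, "0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2}


def write_vcf(cohort: CohortGenotypes, path) -> None:
    path = Path(path)
    chrom_order = list(dict.fromkeys(cohort.variants["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">\n')
        for c in chrom_order:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.samples.index)
            + "\n"
        )
        has_dpgq = cohort.dp is not None and cohort.gq is not None
        v = cohort.variants
        ids = v["variant_id"] if "variant_id" in v else pd.Series(
            [f"v{i}" for i in range(len(v))]
        )
        for j in range(cohort.n_variants):
            if has_dpgq:
                fields = [
                    f"{_GT_CODE[int(g)]}:{int(d)}:{int(q)}"
                    for g, d, q in zip(cohort.gt[:, j], cohort.dp[:, j], cohort.gq[:, j])
                ]
                fmt = "GT:DP:GQ"
            else:
                fields = [_GT_CODE[int(g)] for g in cohort.gt[:, j]]
                fmt = "GT"
            ac = int(np.where(cohort.gt[:, j] > 0, cohort.gt[:, j], 0).sum())
            fh.write(
                f"{v['chrom'].iloc[j]}\t{int(v['pos'].iloc[j])}\t{ids.iloc[j]}\t"
                f"{v['ref'].iloc[j]}\t{v['alt'].iloc[j]}\t.\tPASS\tAC={ac}\t{fmt}\t"
                + "\t".join(fields)
                + "\n"
            )


def read_vcf(path) -> CohortGenotypes:
    """Read an uncompressed VCF (GT[:DP[:GQ]]) into a cohort container."""
    import pysam

    vf = pysam.VariantFile(str(path))
    sample_ids = list(vf.header.samples)
    rows, gt_cols, dp_cols, gq_cols = [], [], [], []
    has_dp = has_gq = True
    for rec in vf:
        rows.append(
            (rec.chrom, rec.pos, rec.id or ".", rec.ref, rec.alts[0])
        )
        g = np.empty(len(sample_ids), dtype=np.int8)
        d = np.zeros(len(sample_ids), dtype=np.int16)
        q = np.zeros(len(sample_ids), dtype=np.int16)
        for i, s in enumerate(sample_ids):
            call = rec.samples[s]
            alleles = call.get("GT")
            if alleles is None or any(a is None for a in alleles):
                g[i] = -1
            else:
                g[i] = sum(1 for a in alleles if a and a > 0)
            if call.get("DP") is not None:
                d[i] = call["DP"]
            else:
                has_dp = False
            if call.get("GQ") is not None:
                q[i] = call["GQ"]
            else:
                has_gq = False
        gt_cols.append(g)
        dp_cols.append(d)
        gq_cols.append(q)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "variant_id", "ref", "alt"])
    gt = np.column_stack(gt_cols) if gt_cols else np.zeros((len(sample_ids), 0), np.int8)
    cohort = CohortGenotypes(
        gt=gt,
        samples=pd.DataFrame(index=pd.Index(sample_ids, name="sample_id")),
        variants=variants,
        dp=np.column_stack(dp_cols) if (gt_cols and has_dp) else None,
        gq=np.column_stack(gq_cols) if (gt_cols and has_gq) else None,
    )
    cohort.variants["cohort_ac"] = cohort.allele_counts()
    return cohort


def write_bed(intervals: pd.DataFrame, path) -> None:
    intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_sv_tsv(svset: SVCallSet, path) -> None:
    codes = np.array(["0/0", "0/1", "1/1"], dtype=object)
    gt_str = codes[np.clip(svset.gt.T, 0, 2)]
    gt_str[svset.gt.T < 0] = "./."
    gt_df = pd.DataFrame(gt_str, columns=svset.samples.index,
                         index=svset.records.index)
    pd.concat([svset.records, gt_df], axis=1).to_csv(path, sep="\t", index=False)


def read_sv_tsv(path) -> SVCallSet:
    df = pd.read_csv(path, sep="\t")
    meta_cols = [c for c in df.columns if not c.startswith("S")]
    sample_cols = [c for c in df.columns if c.startswith("S")]
    gt = np.zeros((len(sample_cols), len(df)), dtype=np.int8)
    for i, c in enumerate(sample_cols):
        gt[i] = df[c].map(_GT_PARSE).to_numpy()
    records = df[meta_cols].copy()
    records["chrom"] = records["chrom"].astype(str)
    return SVCallSet(
        records=records,
        gt=gt,
        samples=pd.DataFrame(index=pd.Index(sample_cols, name="sample_id")),
    )


def write_grm(grm, path_prefix) -> None:
    """GRM as a TSV matrix plus a .ids sidecar (one sample id per line)."""
    prefix = Path(path_prefix)
    np.savetxt(prefix.with_suffix(".grm.tsv"), grm.values, delimiter="\t")
    prefix.with_suffix(".grm.ids").write_text(
        "\n".join(str(s) for s in grm.sample_ids) + "\n"
    )


def read_grm(path_prefix):
    from .heritability import GRMatrix

    prefix = Path(path_prefix)
    values = np.loadtxt(prefix.with_suffix(".grm.tsv"), delimiter="\t")
    ids = prefix.with_suffix(".grm.ids").read_text().splitlines()
    return GRMatrix(values=values, n_variants=0, sample_ids=ids)


def write_phenotypes(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def echo_config(config, path) -> None:
    from dataclasses import asdict

    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
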