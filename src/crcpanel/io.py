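"""Readers and writers for the pipeline's file formats.

Tabular interchange uses tab-separated files with documented headers:

* MAF-like somatic variants: ``sample_id, gene, chrom, pos, ref, alt,
  variant_class, impact, vaf, alt_reads, filter_status, protein_change``
* clinical table: ``patient_id, age, sex, stage, grade, pT, pN, pM,
  sidedness, resection, regimen, response, rfs_months, rfs_event,
  os_months, os_event``
* SEG-like CNV segments: ``sample_id, chrom, start, end, n_bins,
  bin_log2 (comma-separated), baf``
* genotype matrix: variants × patients, first column ``variant_id``.

VCF reading goes through pysam; FASTA reading through pyfaidx. VCF/FASTA
writing emits plain text (VCFv4.2, wrapped FASTA).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

MAF_COLUMNS = [
    "sample_id", "gene", "chrom", "pos", "ref", "alt", "variant_class",
    "impact", "vaf", "alt_reads", "filter_status", "protein_change",
]

SEG_COLUMNS = ["sample_id", "chrom", "start", "end", "n_bins", "bin_log2", "baf"]


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def write_maf(variants: pd.DataFrame, path) -> None:
    cols = [c for c in MAF_COLUMNS if c in variants.columns]
    variants[cols].to_csv(path, sep="\t", index=False)


def read_maf(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_seg(segments: pd.DataFrame, path) -> None:
    seg = segments.copy()
    seg["bin_log2"] = seg["bin_log2"].map(
        lambda b: b if isinstance(b, str) else ",".join(f"{x:.6g}" for x in b)
    )
    seg[SEG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_seg(path) -> pd.DataFrame:
    seg = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    seg["bin_log2"] = seg["bin_log2"].map(
        lambda s: [float(x) for x in str(s).split(",") if x != ""]
    )
    return seg


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_vcf(records: pd.DataFrame, path, contigs: dict[str, int] | None = None,
              sample_columns: list[str] | None = None) -> None:
    """Minimal VCFv4.2 writer.

    ``records`` needs columns ``chrom, pos, id, ref, alt`` and optionally
    ``qual, filter, info``; ``sample_columns`` adds a GT FORMAT block with
    genotypes coded 0/1/2/-1 (−1 → ``./.``).
    """
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=crcpanel\n')
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        if sample_columns:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if sample_columns:
            header += ["FORMAT"] + list(sample_columns)
        fh.write("\t".join(header) + "\n")
        for _, r in records.iterrows():
            row = [
                str(r["chrom"]), str(int(r["pos"])), str(r.get("id", ".")),
                str(r["ref"]), str(r["alt"]), str(r.get("qual", ".")),
                str(r.get("filter", "PASS")), str(r.get("info", ".")),
            ]
            if sample_columns:
                row.append("GT")
                row += [gt_map[int(r[s])] for s in sample_columns]
            fh.write("\t".join(row) + "\n")


def read_vcf(path) -> pd.DataFrame:
    """Read a VCF into a tidy frame (one row per record) via pysam."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            row = {
                "chrom": rec.chrom, "pos": rec.pos, "id": rec.id,
                "ref": rec.ref, "alt": ",".join(rec.alts or ()),
                "filter": ";".join(rec.filter.keys()) or "PASS",
            }
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    row[s] = -1
                else:
                    row[s] = int(sum(gt))
            rows.append(row)
    return pd.DataFrame(rows)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="list")
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=default))


def read_json(path):
    return json.loads(Path(path).read_text())
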