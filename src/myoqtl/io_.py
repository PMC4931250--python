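"""Readers, writers and validation for the pipeline's file formats.

TSV dialect: tab-separated, mandatory header row, '.' for missing values.
VCF is 4.2 with GT and DS FORMAT fields (DS takes priority when reading).
Chromatin segmentations are BED4 (chrom, start, end, state), 0-based
half-open.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import CHROMATIN_STATES, ChromatinSegmentation, GeneAnnotation, GenotypeMatrix

__all__ = [
    "ValidationReport",
    "read_vcf",
    "write_vcf",
    "read_bed_states",
    "write_bed_states",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_gene_annotation",
    "write_gene_annotation",
    "write_table",
    "read_table",
    "write_manifest",
]

MISSING = "."


@dataclass
class ValidationReport:
    """Per-file record counts and the first rejected lines with reasons."""

    file: str
    n_records: int = 0
    n_rejected: int = 0
    offending: list[tuple[str, str]] = field(default_factory=list)  # (line, reason)

    def reject(self, line: str, reason: str) -> None:
        self.n_rejected += 1
        if len(self.offending) < 10:
            self.offending.append((line.strip()[:200], reason))

    def notes(self) -> str:
        lines = [f"{self.file}: {self.n_records} records, {self.n_rejected} rejected"]
        lines += [f"  {reason}: {line}" for line, reason in self.offending]
        return "\n".join(lines)


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write a VCF 4.2 with GT (hard call from rounded dosage) and DS fields."""
    path = Path(path)
    var = genotypes.variants
    contigs = list(dict.fromkeys(var["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            length = int(var.loc[var["chrom"] == c, "pos"].max() + 100_000)
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        gt_codes = ("0/0", "0/1", "1/1")
        for i, row in enumerate(var.itertuples()):
            dos = genotypes.dosages[i]
            hard = np.clip(np.rint(dos).astype(int), 0, 2)
            fields = [
                f"{gt_codes[h]}:{d:g}" for h, d in zip(hard, dos)
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\tPASS\t.\t"
                "GT:DS\t" + "\t".join(fields) + "\n"
            )


def read_vcf(path) -> tuple[GenotypeMatrix, ValidationReport]:
    """Read a VCF into a GenotypeMatrix; DS preferred over GT.

    Multi-allelic records and records missing both GT and DS are rejected
    and counted in the validation report.
    """
    import pysam

    report = ValidationReport(file=str(path))
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    rows = []
    dosages = []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            report.reject(str(rec).strip(), "multi-allelic or missing ALT")
            continue
        ds_row = np.empty(len(samples))
        ok = True
        for j, s in enumerate(samples):
            sample = rec.samples[s]
            ds = sample.get("DS")
            if ds is not None:
                ds_row[j] = float(ds)
            else:
                gt = sample.get("GT")
                if gt is None or any(a is None for a in gt):
                    ok = False
                    break
                ds_row[j] = float(sum(gt))
        if not ok:
            report.reject(str(rec).strip(), "missing both GT and DS")
            continue
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "id": rec.id or f"{rec.chrom}:{rec.pos}",
                "ref": rec.ref,
                "alt": rec.alts[0],
            }
        )
        dosages.append(ds_row)
        report.n_records += 1
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    dos = np.array(dosages) if dosages else np.empty((0, len(samples)))
    gm = GenotypeMatrix(variants=variants, dosages=dos, sample_ids=samples)
    return gm, report


def write_bed_states(segmentation: ChromatinSegmentation, path) -> None:
    segmentation.intervals.to_csv(
        path, sep="\t", header=False, index=False, columns=["chrom", "start", "end", "state"]
    )


def read_bed_states(
    path, tissue_id: str | None = None
) -> tuple[ChromatinSegmentation, ValidationReport]:
    """Read a BED4 segmentation; rejects bad intervals, sorts if needed."""
    path = Path(path)
    report = ValidationReport(file=str(path))
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                report.reject(line, "fewer than 4 BED columns")
                continue
            chrom, start_s, end_s, state = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                report.reject(line, "non-integer coordinates")
                continue
            if end <= start:
                report.reject(line, "end <= start")
                continue
            if state not in CHROMATIN_STATES:
                report.reject(line, f"unknown state {state!r}")
                continue
            rows.append((chrom, start, end, state))
            report.n_records += 1
    iv = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    sorted_iv = iv.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    if not iv.equals(sorted_iv):
        report.offending.append(("", "input not sorted; sorted on read"))
    seg = ChromatinSegmentation(
        tissue_id=tissue_id or Path(path).stem, intervals=sorted_iv
    )
    return seg, report


def write_matrix_tsv(matrix: pd.DataFrame, path, index_name: str = "gene_id") -> None:
    out = matrix.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", na_rep=MISSING)


def read_matrix_tsv(path, index_col: str | int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=[MISSING])


def write_gene_annotation(genes: GeneAnnotation, path) -> None:
    df = genes.genes.copy()
    df["tss_list"] = df["tss_list"].map(lambda t: ",".join(str(x) for x in t))
    df.to_csv(path, sep="\t", index=False)


def read_gene_annotation(path, anchor_rule: str = "most_upstream") -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"tss_list": str})
    df["tss_list"] = df["tss_list"].map(
        lambda t: tuple(int(x) for x in str(t).split(","))
    )
    return GeneAnnotation(genes=df, anchor_rule=anchor_rule)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep=MISSING)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[MISSING])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, seed: int, inputs: list | None = None) -> None:
    """YAML run manifest: effective config, seed, package version, input hashes."""
    from . import __version__

    manifest = {
        "config": config,
        "seed": seed,
        "version": __version__,
        "inputs": {
            str(p): _sha256(Path(p)) for p in (inputs or []) if Path(p).exists()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
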