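"""VCF and table I/O for annotated small variants.

Annotations travel on INFO fields of a single-sample VCF 4.2 file (one
file per individual); genotype quality, depth and allelic depths come from
the FORMAT fields of that sample. INFO key names are configurable; the
defaults are:

======= =====================================================
GENE     gene symbol
CSQ_SO   Sequence Ontology consequence term
AF_EXAC  max allele frequency across ExAC populations
AF_1KG   max allele frequency across 1000 Genomes populations
CLNSIG   ClinVar assertion
CLNREVSTAT  ClinVar review level as a star count (0-4)
CLNSUBS  ClinVar submission count
HGMD_DM  flag: HGMD disease-mutation status
CADD_PHRED  Phred-scaled CADD score
TRUNC_FRAC  fraction of the canonical transcript truncated
======= =====================================================

Reading uses cyvcf2; writing emits plain text so synthetic fixtures stay
diffable.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from cyvcf2 import VCF

from .variants import AnnotatedVariant, ClinvarAssertion, Disposition

__all__ = ["VcfKeys", "write_variants_vcf", "read_variants_vcf",
           "retained_table", "write_sv_table", "read_sv_table"]


@dataclass(frozen=True)
class VcfKeys:
    gene: str = "GENE"
    so: str = "CSQ_SO"
    af_exac: str = "AF_EXAC"
    af_1kg: str = "AF_1KG"
    clnsig: str = "CLNSIG"
    clnrevstat: str = "CLNREVSTAT"
    clnsubs: str = "CLNSUBS"
    hgmd_dm: str = "HGMD_DM"
    cadd: str = "CADD_PHRED"
    trunc_frac: str = "TRUNC_FRAC"


_HEADER_INFO = [
    ("gene", "String", "Gene symbol"),
    ("so", "String", "Sequence Ontology consequence"),
    ("af_exac", "Float", "Max ExAC allele frequency"),
    ("af_1kg", "Float", "Max 1000 Genomes allele frequency"),
    ("clnsig", "String", "ClinVar assertion"),
    ("clnrevstat", "Integer", "ClinVar review stars"),
    ("clnsubs", "Integer", "ClinVar submission count"),
    ("hgmd_dm", "Flag", "HGMD disease mutation status"),
    ("cadd", "Float", "Phred-scaled CADD score"),
    ("trunc_frac", "Float", "Fraction of canonical transcript truncated"),
]


def write_variants_vcf(
    variants: Sequence[AnnotatedVariant],
    path: str | Path,
    sample_id: str | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write one individual's variants as a single-sample VCF 4.2 file.

    All records must belong to the same individual (or ``sample_id`` must
    be given explicitly for an empty list).
    """
    keys = VcfKeys()
    ids = {v.individual_id for v in variants}
    if len(ids) > 1:
        raise ValueError(f"one VCF per individual; got {sorted(ids)}")
    sample = sample_id or (next(iter(ids)) if ids else "SAMPLE")
    contigs: dict[str, int] = dict(contig_lengths or {})
    for v in variants:
        contigs[v.contig] = max(contigs.get(v.contig, 0), v.position + 1000)

    lines = ["##fileformat=VCFv4.2", "##source=cpgpipe-synthetic"]
    for contig in sorted(contigs):
        lines.append(f"##contig=<ID={contig},length={contigs[contig]}>")
    for attr, vtype, desc in _HEADER_INFO:
        num = "0" if vtype == "Flag" else "1"
        lines.append(
            f"##INFO=<ID={getattr(keys, attr)},Number={num},Type={vtype},"
            f'Description="{desc}">'
        )
    lines += [
        '##FILTER=<ID=LowQual,Description="Caller quality filter">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample,
    ]
    for v in sorted(variants, key=lambda v: (v.contig, v.position, v.alt)):
        info = [f"{keys.gene}={v.gene_symbol}", f"{keys.so}={v.so_consequence}"]
        if v.af_exac is not None:
            info.append(f"{keys.af_exac}={v.af_exac:.6g}")
        if v.af_1kg is not None:
            info.append(f"{keys.af_1kg}={v.af_1kg:.6g}")
        if v.clinvar_assertion != ClinvarAssertion.ABSENT:
            info.append(f"{keys.clnsig}={v.clinvar_assertion.value}")
            info.append(f"{keys.clnrevstat}={v.clinvar_stars}")
            info.append(f"{keys.clnsubs}={v.clinvar_submission_count}")
        if v.hgmd_dm:
            info.append(keys.hgmd_dm)
        if v.cadd_phred is not None:
            info.append(f"{keys.cadd}={v.cadd_phred:.4g}")
        if v.truncation_fraction is not None:
            info.append(f"{keys.trunc_frac}={v.truncation_fraction:.6g}")
        gt = "1/1" if v.zygosity == "hom" else "0/1"
        gq = int(round(v.gq)) if v.gq is not None else "."
        dp = v.dp if v.dp is not None else "."
        if v.dp is not None and v.alt_depth is not None:
            ad = f"{v.dp - v.alt_depth},{v.alt_depth}"
        else:
            ad = "."
        lines.append("\t".join([
            v.contig, str(v.position), ".", v.ref, v.alt, ".",
            v.filter_status, ";".join(info),
            "GT:GQ:DP:AD", f"{gt}:{gq}:{dp}:{ad}",
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_variants_vcf(
    path: str | Path,
    individual_id: str | None = None,
    keys: VcfKeys | None = None,
) -> list[AnnotatedVariant]:
    """Read a single-sample annotated VCF into variant records.

    ``individual_id`` overrides the VCF sample name.
    """
    keys = keys or VcfKeys()
    vcf = VCF(str(path))
    if len(vcf.samples) != 1:
        raise ValueError(f"expected a single-sample VCF, got {vcf.samples}")
    iid = individual_id or vcf.samples[0]
    out: list[AnnotatedVariant] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError("multi-allelic records must be split upstream")
        clnsig = rec.INFO.get(keys.clnsig)
        stars = rec.INFO.get(keys.clnrevstat)
        gq = rec.gt_quals[0] if rec.gt_quals is not None else None
        dp = None
        alt_depth = None
        ad = rec.format("AD")
        if ad is not None and ad[0][0] >= 0:
            dp = int(ad[0].sum())
            alt_depth = int(ad[0][1])
        fmt_dp = rec.format("DP")
        if fmt_dp is not None and int(fmt_dp[0][0]) >= 0:
            dp = int(fmt_dp[0][0])
        gts = rec.genotypes[0][:-1]
        zygosity = "hom" if len(gts) == 2 and gts[0] == gts[1] == 1 else "het"
        out.append(AnnotatedVariant(
            contig=rec.CHROM,
            position=rec.POS,
            ref=rec.REF,
            alt=rec.ALT[0],
            gene_symbol=rec.INFO.get(keys.gene, ""),
            so_consequence=rec.INFO.get(keys.so, ""),
            individual_id=iid,
            zygosity=zygosity,
            gq=float(gq) if gq is not None and gq >= 0 else None,
            dp=dp,
            alt_depth=alt_depth,
            filter_status=rec.FILTER or "PASS",
            af_exac=rec.INFO.get(keys.af_exac),
            af_1kg=rec.INFO.get(keys.af_1kg),
            clinvar_assertion=(
                ClinvarAssertion(clnsig) if clnsig else ClinvarAssertion.ABSENT
            ),
            clinvar_stars=int(stars) if stars is not None else None,
            clinvar_submission_count=int(rec.INFO.get(keys.clnsubs, 0) or 0),
            hgmd_dm=bool(rec.INFO.get(keys.hgmd_dm, False)),
            cadd_phred=rec.INFO.get(keys.cadd),
            truncation_fraction=rec.INFO.get(keys.trunc_frac),
        ))
    return out


def retained_table(
    retained: Sequence[AnnotatedVariant],
    dispositions: dict[tuple, Disposition],
) -> pd.DataFrame:
    """Retained variants with their full reason-code audit as a frame."""
    rows = []
    for v in retained:
        d = dispositions[v.key]
        rows.append({
            "individual_id": v.individual_id, "contig": v.contig,
            "position": v.position, "ref": v.ref, "alt": v.alt,
            "gene": v.gene_symbol, "consequence": v.so_consequence,
            "zygosity": v.zygosity, "stage": d.stage.value,
            "outcome": d.outcome.value, "reasons": ";".join(d.reason_codes),
        })
    columns = ["individual_id", "contig", "position", "ref", "alt", "gene",
               "consequence", "zygosity", "stage", "outcome", "reasons"]
    return pd.DataFrame(rows, columns=columns)


_SV_COLUMNS = ["call_id", "caller", "sv_type", "contig_a", "start_a",
               "contig_b", "end_b", "quality", "cohort_frequency",
               "zygosity", "individual_id"]


def write_sv_table(svs, path: str | Path) -> None:
    """BEDPE-like TSV of SV calls (1-based inclusive coordinates)."""
    df = pd.DataFrame(
        [{c: getattr(s, c) for c in _SV_COLUMNS} for s in svs],
        columns=_SV_COLUMNS,
    )
    # repr-precision floats so records round-trip exactly
    for col in ("quality", "cohort_frequency"):
        df[col] = df[col].map(repr)
    df.to_csv(path, sep="\t", index=False)


def read_sv_table(path: str | Path):
    from .sv import SVCall

    df = pd.read_csv(path, sep="\t", dtype={"contig_a": str, "contig_b": str},
                     float_precision="round_trip")
    return [
        SVCall(
            caller=row.caller, sv_type=row.sv_type,
            contig_a=row.contig_a, start_a=int(row.start_a),
            contig_b=row.contig_b, end_b=int(row.end_b),
            quality=float(row.quality),
            cohort_frequency=float(row.cohort_frequency),
            individual_id=str(row.individual_id), zygosity=row.zygosity,
            call_id=None if pd.isna(row.call_id) else str(row.call_id),
        )
        for row in df.itertuples()
    ]
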