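"""Readers and writers for the formats the pipeline touches.

Small-variant and structural-variant VCFs are read with cyvcf2 and
normalized into the internal data model; gene models arrive as BED
(0-based half-open, converted on read) or as a 1-based TSV; panels and
coverage summaries are flat TSVs. The frequency database is emitted as a
site-only VCF 4.2 with AC/AN/AF INFO fields.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import IO, Iterable, Mapping

from cyvcf2 import VCF

from .models import (
    CohortCounts,
    CoverageSummary,
    GeneModel,
    Panel,
    StructuralVariantRecord,
    VariantSite,
)


class VcfFormatError(ValueError):
    """Raised for malformed or unsupported VCF content."""


class MultiallelicError(VcfFormatError):
    """Raised for records with >1 ALT allele; decompose with
    ``bcftools norm -m-`` (or equivalent) before loading."""


#: default INFO-field names for annotations; VEP/ClinVar-style dialects
#: can be remapped via ``annotation_field_map``.
DEFAULT_ANNOTATION_MAP = {
    "impact": "IMPACT",
    "clnsig": "CLNSIG",
    "clnrevstat": "CLNREVSTAT",
    "gene": "GENE",
    "reference_af": "REF_AF",
}

#: alternate spellings accepted when the mapped key is absent
_FALLBACKS = {"clnsig": ("CLIN_SIG",), "clnrevstat": ("CLN_REVSTAT",)}


def _info_str(variant, key: str, fallbacks: tuple[str, ...] = ()) -> str | None:
    for k in (key, *fallbacks):
        val = variant.INFO.get(k)
        if val is not None:
            return str(val)
    return None


def read_small_variants(
    vcf_path: str | Path,
    cohort_label: str,
    annotation_field_map: Mapping[str, str] | None = None,
    min_genotyping_rate: float = 0.90,
    declared_cohort_size: int | None = None,
) -> list[VariantSite]:
    """Read a decomposed small-variant VCF into :class:`VariantSite` records.

    Sites with genotyping rate below ``min_genotyping_rate`` and sites
    invariant in the cohort (no alternate alleles called) are dropped.
    Frequency-only VCFs (no genotype columns) are accepted when AC/AN INFO
    fields are present; ``carriers`` is then unavailable.
    """
    amap = dict(DEFAULT_ANNOTATION_MAP)
    if annotation_field_map:
        amap.update(annotation_field_map)

    try:
        vcf = VCF(str(vcf_path), gts012=True)
    except Exception as exc:  # htslib reports the offending content
        raise VcfFormatError(f"cannot parse VCF {vcf_path}: {exc}") from exc

    n_samples = len(vcf.samples)
    sites: list[VariantSite] = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise MultiallelicError(
                f"{v.CHROM}:{v.POS} has {len(v.ALT)} ALT alleles; decompose "
                "multiallelic records (bcftools norm -m-) before loading"
            )
        if n_samples:
            # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=missing
            gts = v.gt_types
            n_missing = int((gts == 3).sum())
            called = n_samples - n_missing
            if called / n_samples < min_genotyping_rate:
                continue
            n_het = int((gts == 1).sum())
            n_hom = int((gts == 2).sum())
            ac, an, carriers = n_het + 2 * n_hom, 2 * called, n_het + n_hom
            size = n_samples
        else:
            ac, an = v.INFO.get("AC"), v.INFO.get("AN")
            if ac is None or an is None:
                raise VcfFormatError(
                    f"{v.CHROM}:{v.POS}: frequency-only VCF requires AC and AN INFO"
                )
            ac, an, carriers, size = int(ac), int(an), None, declared_cohort_size
            if size is not None and an / (2 * size) < min_genotyping_rate:
                continue
        if ac == 0:
            continue  # invariant in the cohort

        gene = _info_str(v, amap["gene"])
        ref_af = v.INFO.get(amap["reference_af"])
        sites.append(
            VariantSite(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=v.ALT[0],
                counts={
                    cohort_label: CohortCounts(
                        ac=ac, an=an, carriers=carriers, cohort_size=size
                    )
                },
                impact=_info_str(v, amap["impact"]),
                clnsig=_info_str(v, amap["clnsig"], _FALLBACKS["clnsig"]),
                clnrevstat=_info_str(v, amap["clnrevstat"], _FALLBACKS["clnrevstat"]),
                gene_ids=gene.split("|") if gene else [],
                reference_af=float(ref_af) if ref_af is not None else None,
            )
        )
    return sites


def read_structural_variants(
    vcf_path: str | Path,
    cohort_label: str,
    declared_cohort_size: int | None = None,
) -> list[StructuralVariantRecord]:
    """Read an SV VCF (SVTYPE/END convention, Smoove-style quality INFO).

    BND records are retained but flagged ``excluded_bnd``; downstream
    analyses skip them. DEL/DUP records must carry DHFFC.
    """
    try:
        vcf = VCF(str(vcf_path), gts012=True)
    except Exception as exc:
        raise VcfFormatError(f"cannot parse VCF {vcf_path}: {exc}") from exc

    n_samples = len(vcf.samples)
    records: list[StructuralVariantRecord] = []
    for v in vcf:
        svtype = v.INFO.get("SVTYPE")
        if svtype not in ("DEL", "DUP", "INV", "BND"):
            raise VcfFormatError(f"{v.CHROM}:{v.POS}: unsupported SVTYPE {svtype!r}")
        end = int(v.INFO.get("END", v.POS)) if svtype != "BND" else v.POS
        if svtype != "BND" and end < v.POS:
            raise VcfFormatError(f"{v.CHROM}:{v.POS}: END {end} < POS")
        dhffc = v.INFO.get("DHFFC")
        if svtype in ("DEL", "DUP") and dhffc is None:
            raise VcfFormatError(
                f"{v.CHROM}:{v.POS} ({svtype} {v.ID or ''}): missing required DHFFC"
            )
        genotypes = None
        if n_samples:
            gts = v.gt_types
            n_het = int((gts == 1).sum())
            n_hom = int((gts == 2).sum())
            called = n_samples - int((gts == 3).sum())
            counts = CohortCounts(
                ac=n_het + 2 * n_hom,
                an=2 * called,
                carriers=n_het + n_hom,
                cohort_size=n_samples,
            )
            genotypes = [int(g) if g != 3 else -1 for g in gts]
            is_het = n_het > 0
        else:
            ac, an = int(v.INFO.get("AC", 0)), int(v.INFO.get("AN", 0))
            counts = CohortCounts(ac=ac, an=an, cohort_size=declared_cohort_size)
            is_het = bool(v.INFO.get("HET", 1))
        records.append(
            StructuralVariantRecord(
                chrom=v.CHROM,
                start=v.POS,
                end=end,
                svtype=svtype,
                mshq=float(v.INFO.get("MSHQ")) if v.INFO.get("MSHQ") is not None else None,
                dhffc=float(dhffc) if dhffc is not None else None,
                split_reads_per_allele=(
                    int(v.INFO.get("SR")) if v.INFO.get("SR") is not None else None
                ),
                is_het_call=is_het,
                counts={cohort_label: counts},
                genotypes=genotypes,
                sv_id=v.ID,
            )
        )
    return records


def read_gene_models(path: str | Path, dialect: str = "auto") -> list[GeneModel]:
    """Read gene models from BED4+ (``dialect='bed'``) or 1-based TSV.

    BED rows are exon intervals grouped by the name column; the CDS is the
    span of a gene's rows, converted to 1-based inclusive coordinates.
    The TSV dialect has a header ``gene_id chrom strand cds_start cds_end
    exons [canonical_tx_length] [is_AR]`` with exons as ``start-end``
    semicolon-separated, all 1-based inclusive.
    """
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        return []
    if dialect == "auto":
        dialect = "tsv1" if lines[0].split("\t")[0] == "gene_id" else "bed"

    if dialect == "bed":
        by_gene: dict[str, list[tuple[int, int]]] = {}
        chroms: dict[str, str] = {}
        for ln in lines:
            f = ln.split()
            if len(f) < 4:
                raise ValueError(f"BED line needs >=4 columns: {ln!r}")
            chrom, start0, end0, name = f[0], int(f[1]), int(f[2]), f[3]
            if end0 <= start0:
                raise ValueError(f"BED interval empty or inverted: {ln!r}")
            by_gene.setdefault(name, []).append((start0 + 1, end0))  # to 1-based
            chroms.setdefault(name, chrom)
        return [
            GeneModel(
                gene_id=g,
                chrom=chroms[g],
                cds_start=min(s for s, _ in ivs),
                cds_end=max(e for _, e in ivs),
                exons=ivs,
            )
            for g, ivs in by_gene.items()
        ]

    header = lines[0].split("\t")
    idx = {name: i for i, name in enumerate(header)}
    genes = []
    for ln in lines[1:]:
        f = ln.split("\t")
        exons = [
            (int(p.split("-")[0]), int(p.split("-")[1]))
            for p in f[idx["exons"]].split(";")
            if p
        ]
        genes.append(
            GeneModel(
                gene_id=f[idx["gene_id"]],
                chrom=f[idx["chrom"]],
                strand=f[idx["strand"]] if "strand" in idx else "+",
                cds_start=int(f[idx["cds_start"]]),
                cds_end=int(f[idx["cds_end"]]),
                exons=exons,
                canonical_tx_length=(
                    int(f[idx["canonical_tx_length"]])
                    if "canonical_tx_length" in idx
                    else 0
                ),
                is_AR=(
                    f[idx["is_AR"]].lower() in ("1", "true", "yes")
                    if "is_AR" in idx
                    else True
                ),
            )
        )
    return genes


def gene_models_to_bed(genes: Iterable[GeneModel]) -> str:
    """Serialise exon intervals back to BED4 (0-based half-open)."""
    out = []
    for g in genes:
        for s, e in g.exons:
            out.append(f"{g.chrom}\t{s - 1}\t{e}\t{g.gene_id}")
    return "\n".join(out) + "\n"


def write_frequency_vcf(
    sites: Iterable[VariantSite], cohort_label: str, out: IO[str] | str | Path
) -> None:
    """Emit a site-only (frequency release) VCF 4.2 with AC/AN/AF INFO.

    Input must be sorted by (chrom block, pos); AF is printed with six
    significant digits so the read-back frequency matches ac/an.
    """
    sites = list(sites)
    seen: list[str] = []
    last_pos = 0
    for s in sites:
        if not seen or s.chrom != seen[-1]:
            if s.chrom in seen:
                raise ValueError(
                    f"unsorted input: chromosome {s.chrom} occurs in two blocks"
                )
            seen.append(s.chrom)
            last_pos = 0
        if s.pos < last_pos:
            raise ValueError(f"unsorted input at {s.chrom}:{s.pos}")
        last_pos = s.pos

    header = [
        "##fileformat=VCFv4.2",
        f"##source=cohortvar frequency release ({cohort_label})",
        '##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count">',
        '##INFO=<ID=AN,Number=1,Type=Integer,Description="Total called alleles">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">',
    ]
    header += [f"##contig=<ID={c}>" for c in seen]
    header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    body = []
    for s in sites:
        c = s.cohort(cohort_label)
        body.append(
            f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\t.\t"
            f"AC={c.ac};AN={c.an};AF={c.af:.6g}"
        )
    text = "\n".join(header + body) + "\n"
    if hasattr(out, "write"):
        out.write(text)
    else:
        Path(out).write_text(text)


def read_panels(path: str | Path) -> list[Panel]:
    """Read a panel-membership TSV (panel_id, panel_name, gene_id)."""
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    idx = {name: i for i, name in enumerate(header)}
    members: dict[str, list[str]] = {}
    names: dict[str, str] = {}
    for ln in lines[1:]:
        if not ln.strip():
            continue
        f = ln.split("\t")
        pid = f[idx["panel_id"]]
        members.setdefault(pid, []).append(f[idx["gene_id"]])
        names.setdefault(pid, f[idx["panel_name"]] if "panel_name" in idx else pid)
    return [Panel(panel_id=p, name=names[p], gene_ids=g) for p, g in members.items()]


def read_coverage(path: str | Path) -> list[CoverageSummary]:
    """Read per-gene coverage TSV (gene_id, frac_below_20x)."""
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    idx = {name: i for i, name in enumerate(header)}
    out = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        f = ln.split("\t")
        out.append(
            CoverageSummary(
                gene_id=f[idx["gene_id"]],
                frac_below_20x=float(f[idx["frac_below_20x"]]),
            )
        )
    return out


def warn_unknown_genes(panels: Iterable[Panel], known: set[str]) -> None:
    for p in panels:
        unknown = [g for g in p.gene_ids if g not in known]
        if unknown:
            warnings.warn(
                f"panel {p.panel_id}: {len(unknown)} gene id(s) not in gene models "
                f"(e.g. {unknown[0]}); retained",
                stacklevel=2,
            )
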