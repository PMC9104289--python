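"""End-to-end orchestration with structured logging and a run manifest.

Each stage logs (stage, count_in, count_out, reason) so cohort-level
narrative numbers ("n excluded because ...") can be reconstructed from
the logs; the manifest records input digests and per-stage counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, clinvar_pathogenic, fst, frequency_db, gene_burden, sv_lof
from . import variant_io

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    version: str
    seed: int | None
    config_hash: str
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def record(self, stage: str, **counts: int) -> None:
        self.stage_counts[stage] = dict(counts)
        logger.info("stage=%s %s", stage, counts)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_all(config: dict, outdir: str | Path) -> RunManifest:
    """Run every stage over the inputs named in ``config``.

    Required config keys: cohort_a, cohort_b (VCF paths), genes
    (BED/TSV), optional sv_a/sv_b, panels, coverage, and parameter keys
    flank, rare_threshold, af_cap, fst_window, maf (defaults as in the
    module functions). All outputs are TSVs under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    required = ["cohort_a", "cohort_b", "genes"]
    optional = ["sv_a", "sv_b", "panels", "coverage"]
    for key in required + [k for k in optional if k in config]:
        if key not in config:
            raise FileNotFoundError(f"config is missing required input {key!r}")
        if not Path(config[key]).exists():
            raise FileNotFoundError(f"input {key!r} not found: {config[key]}")

    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = RunManifest(
        version=__version__,
        seed=config.get("seed"),
        config_hash=cfg_hash,
        input_digests={
            k: _digest(config[k]) for k in required + optional if k in config
        },
    )

    sites_a = variant_io.read_small_variants(
        config["cohort_a"], "a", min_genotyping_rate=config.get("genotyping_rate", 0.90)
    )
    sites_b = variant_io.read_small_variants(
        config["cohort_b"], "b",
        min_genotyping_rate=config.get("genotyping_rate", 0.90),
        declared_cohort_size=config.get("cohort_b_size"),
    )
    manifest.record("read_small_variants", cohort_a=len(sites_a), cohort_b=len(sites_b))

    genes = variant_io.read_gene_models(config["genes"])
    manifest.record("read_gene_models", genes=len(genes))

    # frequency database + spectrum (sequenced cohort)
    variant_io.write_frequency_vcf(sites_a, "a", outdir / "frequency_a.vcf")
    spec = frequency_db.spectrum_table(sites_a, "a")
    (outdir / "spectrum_a.tsv").write_text(spec.to_long_tsv())
    manifest.record("spectrum", sites=spec.total)

    # rare pathogenic selection
    summary = clinvar_pathogenic.select_rare_pathogenic(
        sites_a, cohort_label="a", threshold=config.get("rare_threshold", 0.001)
    )
    path_df = pd.DataFrame(
        [
            {
                "chrom": c.site.chrom,
                "pos": c.site.pos,
                "gene_id": "|".join(c.site.gene_ids),
                "significance": c.significance,
                "confidence_tier": c.confidence_tier,
                "carriers": c.site.cohort("a").carriers,
                "reference_af": c.reference_af,
            }
            for c in summary.calls
        ]
    )
    path_df.to_csv(outdir / "pathogenic_a.tsv", sep="\t", index=False)
    manifest.record(
        "rare_pathogenic",
        selected=summary.total,
        private=summary.n_private or 0,
    )

    coverage = (
        variant_io.read_coverage(config["coverage"]) if "coverage" in config else None
    )
    out = gene_burden.run_gene_burden(
        sites_a,
        sites_b,
        genes,
        coverage=coverage,
        flank=config.get("flank", 5000),
        declared_size_a=config.get("cohort_a_size"),
        declared_size_b=config.get("cohort_b_size"),
    )
    out.results.to_csv(outdir / "gene_burden.tsv", sep="\t", index=False)
    manifest.record(
        "gene_burden",
        genes_in=len(genes),
        tested=len(out.results),
        excluded=len(out.skipped),
        significant=int((out.results["q"] < 0.05).sum()) if len(out.results) else 0,
    )

    if "panels" in config:
        panels = variant_io.read_panels(config["panels"])
        variant_io.warn_unknown_genes(panels, {g.gene_id for g in genes})
        pdf = gene_burden.run_panel_burden(panels, out)
        pdf.to_csv(outdir / "panel_burden.tsv", sep="\t", index=False)
        manifest.record(
            "panel_burden",
            panels_in=len(panels),
            tested=len(pdf),
            significant=int((pdf["q"] < 0.05).sum()) if len(pdf) else 0,
        )

    if "sv_a" in config and "sv_b" in config:
        svs_a = variant_io.read_structural_variants(config["sv_a"], "a")
        svs_b = variant_io.read_structural_variants(config["sv_b"], "b")
        hq_a = sv_lof.filter_high_quality(svs_a)
        hq_b = sv_lof.filter_high_quality(svs_b)
        manifest.record(
            "sv_quality_filter",
            read_a=len(svs_a), read_b=len(svs_b),
            high_quality_a=len(hq_a), high_quality_b=len(hq_b),
        )
        sv_df = sv_lof.sv_gene_burden(
            hq_a, hq_b, genes, af_cap=config.get("af_cap", 0.01)
        )
        sv_df.to_csv(outdir / "sv_lof_burden.tsv", sep="\t", index=False)
        manifest.record("sv_lof_burden", genes=len(sv_df))

    if config.get("fst_sites"):
        # site components supplied by the synthetic generator or upstream
        comps = config["fst_sites"]
        pruned = fst.maf_prune(comps, threshold=config.get("maf", 0.01))
        wins = fst.fst_windows(pruned, window=config.get("fst_window", 1000))
        wins.to_csv(outdir / "fst_windows.tsv", sep="\t", index=False)
        manifest.record(
            "fst", sites_in=len(comps), after_maf_prune=len(pruned), windows=len(wins)
        )

    manifest.write(outdir / "manifest.json")
    return manifest
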