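"""End-to-end orchestration: simulate -> mask -> summarize -> differential
expression -> curate -> enrichment, with every intermediate written as plain
text and a deterministic JSON summary of the headline numbers.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, enrichment, expression, io, masking
from .curation import build_obbmst, case_convention_map, curate, GeneSignature, harmonize_symbols
from .simulate import (
    DE_GROUPS,
    SimulationConfig,
    generate_promoters,
    generate_signature_registry,
    generate_two_species_reference,
    simulate_experiment,
    mouse_symbol,
)


def default_motifs() -> list[enrichment.MotifModel]:
    """The synthetic PWMs shipped with the package (see data/motifs.meme)."""
    ref = importlib.resources.files("xenostroma").joinpath("data/motifs.meme")
    with importlib.resources.as_file(ref) as path:
        return enrichment.read_motifs(path)


def fixture_config() -> SimulationConfig:
    """The small packaged study configuration used by `run-all` demos/tests."""
    ref = importlib.resources.files("xenostroma").joinpath("data/fixture.yaml")
    with importlib.resources.as_file(ref) as path:
        return SimulationConfig.from_yaml(path)


def _round(x: float, nd: int = 6) -> float:
    return float(round(float(x), nd))


def run_all(
    config: SimulationConfig,
    outdir: str | Path | None = None,
    motif_rate_cluster: float = 0.6,
    motif_rate_background: float = 0.3,
    promoter_window: int = 2000,
    n_resamples: int = 5000,
) -> dict:
    """Run the full pipeline on a synthetic dataset and return the summary.

    All randomness derives from ``config.seed``.  When ``outdir`` is given,
    inputs, intermediates and the summary are written there as plain text.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- simulate
    ref = generate_two_species_reference(config)
    intensities, design = simulate_experiment(config, ref.chipdef, ref.truth)
    registry = generate_signature_registry(ref.truth, config)
    if out is not None:
        io.write_fasta(ref.mouse_transcripts, out / "mouse_transcripts.fa")
        io.write_fasta(ref.human_transcripts, out / "human_transcripts.fa")
        ref.chipdef.to_tsv(out / "chip.tsv")
        ref.truth.to_json(out / "truth.json")
        io.write_tsv(intensities, out / "intensities.tsv")
        io.write_tsv(design, out / "design.tsv")
        io.write_gmt(registry.signatures, out / "signatures.gmt")
        io.write_tsv(
            pd.DataFrame(sorted(registry.categories.items()), columns=["signature", "category"]),
            out / "signature_categories.tsv", index=False,
        )

    # --- mask
    report = masking.scan_cross_hybridization(ref.chipdef, ref.human_transcripts)
    masked = masking.redefine_probesets(ref.chipdef, report)
    flagged = report.flagged_probes()
    planted = set(ref.truth.crosshyb_probes)
    n_probes = ref.chipdef.n_probes
    tp = len(flagged & planted)
    fp = len(flagged - planted)
    sens = tp / len(planted) if planted else 1.0
    spec = 1.0 - fp / (n_probes - len(planted)) if n_probes > len(planted) else 1.0
    if out is not None:
        report.to_tsv(out / "crosshyb_report.tsv")
        masked.to_tsv(out / "masked_chip.tsv")

    # --- normalize (retained species-specific probes only) + summarize
    qn = expression.quantile_normalize(intensities.loc[masked.retained_probe_ids])
    expr = expression.summarize_probesets(qn, masked)
    if out is not None:
        io.write_tsv(expr, out / "expression.tsv")

    # --- differential expression per model vs sham
    de_tables: dict[str, pd.DataFrame] = {}
    de_lists: dict[str, pd.DataFrame] = {}
    for model in DE_GROUPS:
        table = diffexpr.moderated_t_test(expr, design, (model, "sham"))
        table = diffexpr.add_lfdr(table)
        de_tables[model] = table
        de_lists[model] = diffexpr.select_de(table, model)
        if out is not None:
            io.write_tsv(table, out / f"de_{model}.tsv")

    obbmst = build_obbmst(de_lists[DE_GROUPS[0]], de_lists[DE_GROUPS[1]],
                          model_a=DE_GROUPS[0], model_b=DE_GROUPS[1])

    # --- harmonize the (human-symbol) signature registry to mouse
    universe = [str(g) for g in expr.index]
    ortho = case_convention_map(mouse_symbol(i) for i in range(config.n_genes_per_species))
    mouse_sigs: dict[str, GeneSignature] = {}
    for name, symbols in registry.signatures.items():
        category = registry.categories.get(name, "niche-HSC" if "HSC" in name else "niche-UGM")
        sig = GeneSignature(name=name, species="human", category=category,
                            symbols=tuple(symbols))
        mouse_sigs[name], _ = harmonize_symbols(sig, ortho, "mouse")

    # --- curate
    category_sigs = [mouse_sigs[n] for n in registry.categories]
    ledger = curate(obbmst, category_sigs)
    if out is not None:
        ledger.to_json(out / "curation_ledger.json")

    # --- niche-signature overlaps
    overlaps: dict[str, dict] = {}
    for name in config.niche_signatures:
        sig = mouse_sigs[name]
        for query_name, query in (("obbmst", obbmst.all_genes), ("core", ledger.core)):
            res = enrichment.overlap_test(query, sig.symbols, universe)
            overlaps[f"{name}:{query_name}"] = {
                "k": res.k, "K": res.K, "n": res.n, "N": res.N,
                "coverage_pct": _round(res.coverage, 1), "p": _round(res.p, 9),
                "fold": _round(res.fold, 4),
            }

    # --- promoter motif enrichment on the core cluster
    motif = default_motifs()[0]
    core = sorted(ledger.core)
    motif_summary: dict = {"motif": motif.name, "skipped": True}
    if len(core) >= 5:
        rng = np.random.default_rng([4, config.seed])
        non_members = sorted(set(universe) - set(obbmst.all_genes))
        pool = sorted(rng.choice(non_members, size=min(len(non_members), 2 * len(core)),
                                 replace=False).tolist())
        promoters = generate_promoters(core, pool, motif, motif_rate_cluster,
                                       motif_rate_background, promoter_window,
                                       seed=config.seed)
        if out is not None:
            io.write_fasta(promoters, out / "promoters.fa")
        res = enrichment.motif_enrichment(core, pool, promoters, motif,
                                          n_resamples=n_resamples, seed=config.seed)
        motif_summary = {
            "motif": res.motif,
            "ef": _round(res.ef, 4),
            "p": _round(res.p, 6),
            "freq_cluster": _round(res.freq_cluster, 6),
            "freq_background": _round(res.freq_background, 6),
            "n_resamples": res.n_resamples,
            "reported": bool(res.reported),
            "skipped": False,
        }

    summary = {
        "seed": config.seed,
        "n_genes": config.n_genes_per_species,
        "masking": {
            "n_probes": n_probes,
            "n_planted": len(planted),
            "n_flagged": len(flagged),
            "sensitivity": _round(sens),
            "specificity": _round(spec),
            "n_probesets_dropped": len(masked.dropped_probesets),
        },
        "de": {
            model: {
                "threshold": diffexpr.THRESHOLD_PRESETS[model],
                "n_selected": int(len(de_lists[model])),
                "n_up": int((de_lists[model]["direction"] == "up").sum()),
                "n_down": int((de_lists[model]["direction"] == "down").sum()),
            }
            for model in DE_GROUPS
        },
        "obbmst": {
            "n_total": len(obbmst.all_genes),
            "n_common": len(obbmst.common),
            "n_unique_a": len(obbmst.unique_a),
            "n_unique_b": len(obbmst.unique_b),
            "n_discordant": len(obbmst.discordant),
            "concordance_r2": _round(obbmst.concordance.r_squared)
            if obbmst.concordance else None,
        },
        "curation": {
            "stage_removed": {s.category: len(s.removed) for s in ledger.stages},
            "n_core": len(ledger.core),
            "fractions": {k: _round(v) for k, v in ledger.fractions().items()},
        },
        "overlaps": overlaps,
        "motif": motif_summary,
    }
    if out is not None:
        io.write_json(summary, out / "summary.json")
    return summary
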