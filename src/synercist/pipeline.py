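"""End-to-end orchestration: simulate inputs, run every analysis stage.

``run_pipeline`` chains simulate -> combo-screen -> nes-switch -> venn ->
enrichment -> motif-delta -> integrate -> signature, writing each stage's
tables under its own subdirectory of the output directory plus a JSON run
manifest (config snapshot, seed, per-stage outputs and timings). Given
the same config and seed, every tabular output is byte-identical across
runs.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrichment import (
    chromhmm_enrichment,
    coenrichment_scan,
    gene_class_enrichment,
    pairwise_overlap_significance,
)
from .integrate import build_integration, group_compare
from .intervals import annotate_to_genes, genome_bins, write_bed, write_gene_models
from .motifs import coverage_percent, family_frequency, motif_delta, write_jaspar
from .nes import classify_terms, filter_significant, find_switches, top_terms
from .screen import combo_test, contour_table, normalize_viability
from .signature import association_test, cluster_tumors, select_signature
from .synthetic import (
    SimulationConfig,
    demo_pwms,
    simulate_cistrome_collection,
    simulate_cohort,
    simulate_deg_table,
    simulate_differential_cistromes,
    simulate_gene_models,
    simulate_nes_tables,
    simulate_screen_plate,
    simulate_sequences_with_motifs,
    write_fasta,
)

log = logging.getLogger("synercist")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "genome": [["chr1", 10_000_000], ["chr2", 10_000_000]],
        "n_genes": 2000,
        "n_tumors": 100,
        "plate_noise_sd": 5.0,
        "deg_fraction": 0.2,
        "lfc_sd": 0.4,
        "loss_enhancer_enrichment": 10.0,
        "switch_fraction": 0.1,
        "factors": ["AR", "MYC", "H3K27ac", "ARv7"],
        "n_loss": 300,
        "n_gain": 200,
        "shared_block": 50,
        "doses": [0.0, 0.1, 0.3, 1.0, 3.0, 10.0],
        "embedded_delta": {"dose_a": 0.3, "dose_b": 1.0, "delta": 15.0},
        "n_replicates": 4,
        "deg_coupling": 0.8,
        "n_nes_terms": 500,
        "plant_rate_treatment": 0.4,
        "plant_rate_reference": 0.1,
        "cohort_shift": 3.0,
        "category_strength": 0.9,
    },
    "screen": {"cap": 100.0, "paired": False, "mt_method": "fdr_bh"},
    "nes": {"alpha": 0.05, "top_n": 40},
    "enrich": {"min_bp": 1, "alpha": 0.05, "coenrich_top_n": 40,
               "coenrich_fc": 1.2},
    "motifs": {"score_fraction": 0.9, "family_threshold": 5.0},
    "integrate": {"fc_measure": "log2", "logpv_min": 1.0, "abs_lfc_min": 0.263,
                  "window": 100_000},
    "signature": {"k": 2, "method": "ward", "metric": "euclidean"},
}


def load_config(path) -> dict:
    """Load a YAML pipeline config, filling gaps from the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    config = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


def _write(df: pd.DataFrame, path: Path) -> str:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return str(path)


def run_pipeline(config: dict | None = None, out_dir="pipeline_out",
                 seed: int | None = None) -> dict:
    """Run all stages on simulated inputs; return the run manifest."""
    config = copy.deepcopy(config) if config else copy.deepcopy(DEFAULT_CONFIG)
    if seed is not None:
        config["seed"] = seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config["seed"],
        "config": config,
        "stages": {},
    }

    def stage(name):
        t0 = time.perf_counter()
        log.info("stage=%s status=start", name)
        return t0

    def done(name, t0, outputs: dict):
        manifest["stages"][name] = {
            "outputs": outputs,
            "seconds": round(time.perf_counter() - t0, 3),
        }
        log.info("stage=%s status=done seconds=%.2f", name,
                 time.perf_counter() - t0)

    sim = config["simulate"]
    delta_spec = sim.get("embedded_delta") or {}
    delta_map = (
        {(delta_spec["dose_a"], delta_spec["dose_b"]): delta_spec["delta"]}
        if delta_spec
        else {}
    )
    sc = SimulationConfig(
        seed=config["seed"],
        genome=tuple((c, int(l)) for c, l in sim["genome"]),
        n_genes=sim["n_genes"],
        n_tumors=sim["n_tumors"],
        plate_noise_sd=sim["plate_noise_sd"],
        embedded_delta_map=delta_map,
        deg_fraction=sim["deg_fraction"],
        lfc_sd=sim["lfc_sd"],
        loss_enhancer_enrichment=sim["loss_enhancer_enrichment"],
        switch_fraction=sim["switch_fraction"],
    )

    # ---- simulate ---------------------------------------------------------
    t0 = stage("simulate")
    plate = simulate_screen_plate(
        sc, sim["doses"], sim["doses"], n_replicates=sim["n_replicates"]
    )
    cistromes, segmentation = simulate_differential_cistromes(
        sc, sim["factors"], n_loss=sim["n_loss"], n_gain=sim["n_gain"],
        shared_block=sim["shared_block"],
    )
    genes = simulate_gene_models(sc)
    deg = simulate_deg_table(
        sc, genes, coupled_regions=cistromes[sim["factors"][1]],
        coupling=sim["deg_coupling"],
    )
    nes_a, nes_b = simulate_nes_tables(sc, n_terms=sim["n_nes_terms"])
    sim_dir = out / "simulate"
    sim_dir.mkdir(exist_ok=True)
    control_rows = pd.DataFrame({
        "drugA_dose": 0.0, "drugB_dose": 0.0,
        "replicate": range(1, len(plate.controls) + 1),
        "raw": plate.controls, "is_control": True,
    })
    full_plate = pd.concat(
        [plate.wells.assign(is_control=False), control_rows], ignore_index=True
    )
    outputs = {"plate": _write(full_plate, sim_dir / "plate.tsv")}
    for factor, rset in cistromes.items():
        p = sim_dir / f"cistrome_{factor}.bed"
        write_bed(rset, p)
        outputs[f"cistrome_{factor}"] = str(p)
    write_bed(segmentation, sim_dir / "chromhmm.bed")
    outputs["chromhmm"] = str(sim_dir / "chromhmm.bed")
    write_gene_models(genes, sim_dir / "genes.tsv")
    outputs["genes"] = str(sim_dir / "genes.tsv")
    outputs["deg"] = _write(deg, sim_dir / "deg.tsv")
    outputs["nes_a"] = _write(nes_a, sim_dir / "nes_condA.tsv")
    outputs["nes_b"] = _write(nes_b, sim_dir / "nes_condB.tsv")
    done("simulate", t0, outputs)

    # ---- combination screen ----------------------------------------------
    t0 = stage("combo_screen")
    surface = normalize_viability(plate)
    tested = combo_test(
        surface, cap=config["screen"]["cap"], paired=config["screen"]["paired"],
        mt_method=config["screen"]["mt_method"],
    )
    contour = contour_table(surface)
    done("combo_screen", t0, {
        "combo_delta": _write(tested, out / "screen" / "combo_delta.tsv"),
        "contour": _write(contour, out / "screen" / "contour.tsv"),
    })

    # ---- NES switches -----------------------------------------------------
    t0 = stage("nes_switch")
    alpha = config["nes"]["alpha"]
    switches = find_switches(
        filter_significant(nes_a, alpha), filter_significant(nes_b, alpha)
    )
    classified, freq = classify_terms(switches)
    top = top_terms(classified, config["nes"]["top_n"])
    done("nes_switch", t0, {
        "switches": _write(classified, out / "nes" / "switches.tsv"),
        "word_freq": _write(freq, out / "nes" / "word_frequency.tsv"),
        "top_terms": _write(top, out / "nes" / "top_terms.tsv"),
    })

    # ---- Venn partition ---------------------------------------------------
    t0 = stage("venn")
    from .intervals import venn_partition

    loss_sets = [cistromes[f].subset("loss", f) for f in sim["factors"][:4]]
    membership, counts = venn_partition(loss_sets)
    done("venn", t0, {
        "membership": _write(membership, out / "venn" / "membership.tsv"),
        "counts": _write(counts, out / "venn" / "counts.tsv"),
    })

    # ---- enrichment -------------------------------------------------------
    t0 = stage("enrichment")
    min_bp = config["enrich"]["min_bp"]
    regions_by_fd = {
        (f, d): cistromes[f].subset(d, f"{f}.{d}")
        for f in sim["factors"]
        for d in ("gain", "loss")
    }
    chromhmm = chromhmm_enrichment(regions_by_fd, segmentation, min_bp=min_bp,
                                   alpha=config["enrich"]["alpha"])
    universe = genome_bins(sc.genome_map, width=2000, label="universe")
    pairwise = pairwise_overlap_significance(
        [cistromes[f] for f in sim["factors"]], universe, min_bp
    )
    k27 = sim["factors"][2] if len(sim["factors"]) > 2 else sim["factors"][0]
    ann_k27 = annotate_to_genes(
        cistromes[k27].subset("loss"), genes,
        window=config["integrate"]["window"],
    )
    class_map = {g.symbol: g.gene_class for g in genes}
    gene_cls = gene_class_enrichment(
        ann_k27, class_map, [g.symbol for g in genes],
        alpha=config["enrich"]["alpha"],
    )
    query = cistromes[sim["factors"][0]].subset("loss")
    collection = simulate_cistrome_collection(
        sc, query, factors=["AR", "FOXA1", "MYC", "CTCF", "GATA2"],
        enriched_factors={"AR": 0.5},
    )
    coenrich = coenrichment_scan(
        query, collection, top_n=config["enrich"]["coenrich_top_n"],
        fc_threshold=config["enrich"]["coenrich_fc"],
    )
    done("enrichment", t0, {
        "chromhmm": _write(chromhmm, out / "enrich" / "chromhmm.tsv"),
        "pairwise_overlap": _write(pairwise, out / "enrich" / "pairwise_overlap.tsv"),
        "gene_class": _write(gene_cls, out / "enrich" / "gene_class.tsv"),
        "coenrichment": _write(coenrich, out / "enrich" / "coenrichment.tsv"),
    })

    # ---- motif deltas -----------------------------------------------------
    t0 = stage("motif_delta")
    pwms = demo_pwms()
    planted = pwms[0]  # bHLH family planted more heavily in treatment
    treatment = cistromes[sim["factors"][0]].subset("loss", "treatment")
    reference = cistromes[sim["factors"][0]].subset("gain", "reference")
    seqs_t = simulate_sequences_with_motifs(
        sc, treatment, planted, sim["plant_rate_treatment"]
    )
    seqs_r = simulate_sequences_with_motifs(
        sc, reference, planted, sim["plant_rate_reference"]
    )
    motif_dir = out / "motifs"
    motif_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(seqs_t, motif_dir / "treatment.fa")
    write_fasta(seqs_r, motif_dir / "reference.fa")
    write_jaspar(pwms, motif_dir / "pwms.jaspar")
    frac = config["motifs"]["score_fraction"]
    names_t = [iv.name for iv in treatment]
    names_r = [iv.name for iv in reference]
    deltas = {}
    rows = []
    for pwm in pwms:
        cov_t = coverage_percent(names_t, seqs_t, pwm, "treatment", frac)
        cov_r = coverage_percent(names_r, seqs_r, pwm, "reference", frac)
        deltas[pwm.motif_id] = motif_delta(cov_t, cov_r)
        rows.append({
            "motif": pwm.motif_id, "factor": pwm.factor, "family": pwm.family,
            "coverage_treatment": cov_t.coverage_percent,
            "coverage_reference": cov_r.coverage_percent,
            "delta": deltas[pwm.motif_id],
        })
    family_map = {p.motif_id: p.family for p in pwms}
    families, _ = family_frequency(deltas, family_map,
                                   config["motifs"]["family_threshold"])
    done("motif_delta", t0, {
        "coverage": _write(pd.DataFrame(rows), motif_dir / "coverage_delta.tsv"),
        "families": _write(families, motif_dir / "family_summary.tsv"),
    })

    # ---- integration ------------------------------------------------------
    t0 = stage("integrate")
    records_all = []
    for factor in ("AR", "MYC", "H3K27ac"):
        if factor not in cistromes:
            continue
        ann = annotate_to_genes(
            cistromes[factor], genes, window=config["integrate"]["window"]
        )
        rec = build_integration(
            ann, deg, factor=factor,
            fc_measure=config["integrate"]["fc_measure"],
            logpv_min=config["integrate"]["logpv_min"],
            abs_lfc_min=config["integrate"]["abs_lfc_min"],
        )
        records_all.append(rec)
    records = pd.concat(records_all, ignore_index=True)
    groups = group_compare(records)
    done("integrate", t0, {
        "records": _write(records, out / "integrate" / "records.tsv"),
        "group_tests": _write(groups, out / "integrate" / "group_tests.tsv"),
    })

    # ---- signature / cohort ----------------------------------------------
    t0 = stage("signature")
    selection = select_signature(records)
    cohort, subtype = simulate_cohort(
        sc, selection.union or [g.symbol for g in genes[:50]],
        shift=sim["cohort_shift"], category_strength=sim["category_strength"],
    )
    clusters = cluster_tumors(
        cohort, list(cohort.zscores.index), k=config["signature"]["k"],
        method=config["signature"]["method"], metric=config["signature"]["metric"],
    )
    ar_test = association_test(clusters, cohort.ar_category)
    ne_test = association_test(clusters, cohort.ne_category)
    sig_dir = out / "signature"
    sig_dir.mkdir(parents=True, exist_ok=True)
    sig_df = pd.DataFrame(
        [(rule, g) for rule, gl in selection.rule_genes.items() for g in gl],
        columns=["rule", "gene"],
    )
    cohort.write(sig_dir / "cohort_zscores.tsv", sig_dir / "cohort_labels.tsv")
    tests = pd.DataFrame([
        {"score": "AR", "chi2": ar_test["chi2"], "df": ar_test["df"],
         "p": ar_test["p"], "yates": ar_test["yates"]},
        {"score": "NE", "chi2": ne_test["chi2"], "df": ne_test["df"],
         "p": ne_test["p"], "yates": ne_test["yates"]},
    ])
    done("signature", t0, {
        "signature_genes": _write(sig_df, sig_dir / "signature_genes.tsv"),
        "clusters": _write(
            clusters.rename_axis("tumor").reset_index(), sig_dir / "clusters.tsv"
        ),
        "association": _write(tests, sig_dir / "association.tsv"),
        "n_signature_genes": len(selection.union),
    })

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
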