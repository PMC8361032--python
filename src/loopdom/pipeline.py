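"""End-to-end orchestration of the synthetic benchmark with a run manifest.

``run_all`` simulates every input, executes each analysis stage, writes all
stage outputs as plain-text files and records a manifest with the config
snapshot, seed, per-file SHA-256 hashes, stage timings and package version.
All stages are deterministic under a fixed seed; timings are the only
non-reproducible manifest field.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .domains import (Domain, DomainCallParams, Loop, call_domains,
                      constitutive_domains)
from .genomics import GenomicInterval
from .features import variant_density, compare_motif_conservation
from .genomics import write_bed, write_bedpe, write_contacts, write_table
from .simulate import (SimConfig, default_config, jaccard_domains,
                       precision_recall, random_motifs, score_domain_recovery,
                       simulate_annotation, simulate_expression, simulate_hic,
                       simulate_multisample_domains,
                       simulate_tracks_and_variants, _loop_span)
from .specificity import (call_specific_regulators, coactivation_correlation,
                          compare_coactivation, filter_active,
                          normalize_enhancer_signal)
from .tig import classify_domains, permutation_enrichment
from .virtual4c import aggregate_profiles, boundary_profile

__all__ = ["run_all"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _domains_frame(domains, samples=None) -> pd.DataFrame:
    rows = []
    for i, d in enumerate(domains):
        row = {
            "chrom1": d.left.chrom, "start1": d.left.start, "end1": d.left.end,
            "chrom2": d.right.chrom, "start2": d.right.start, "end2": d.right.end,
            "summit_start1": d.summit_left.start, "summit_end1": d.summit_left.end,
            "summit_start2": d.summit_right.start, "summit_end2": d.summit_right.end,
            "best_p": d.best_p, "members": d.member_count,
            "gene_count": d.gene_count if d.gene_count is not None else "",
            "class": d.klass or "",
        }
        if d.presence is not None:
            row["presence"] = "".join("1" if x else "0" for x in d.presence)
            row["constitutive"] = int(bool(d.constitutive))
        rows.append(row)
    return pd.DataFrame(rows)


def planted_truth_domains(cfg: SimConfig, best_p: float = 1e-12) -> list[Domain]:
    """Planted loops rendered as Domain objects (anchors = anchor bins)."""
    out = []
    for pl in cfg.planted_loops:
        bs = cfg.bin_size
        left = GenomicInterval(pl.chrom, pl.bin_i * bs, (pl.bin_i + 1) * bs)
        right = GenomicInterval(pl.chrom, pl.bin_j * bs, (pl.bin_j + 1) * bs)
        loop = Loop(left, right, p_value=best_p)
        out.append(Domain(left, right, left, right, best_p, (loop,)))
    return out


def run_all(out_dir: str | Path, seed: int = 0,
            cfg: SimConfig | None = None, n_perm: int = 999,
            flank_bins: int = 10) -> dict:
    """Simulate all inputs, run every stage, write outputs and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg is None:
        cfg = default_config(seed=seed)
    manifest: dict = {"version": __version__, "seed": seed,
                      "config": dataclasses.asdict(cfg), "stages": {}}
    summary: dict = {}

    def _stage(name):
        t0 = time.perf_counter()
        return lambda files: manifest["stages"].update(
            {name: {"seconds": round(time.perf_counter() - t0, 3),
                    "files": {f: _sha256(out / f) for f in files}}})

    # --- simulate contacts + annotation -----------------------------------
    done = _stage("simulate")
    matrices, planted = simulate_hic(cfg)
    annot = simulate_annotation(cfg)
    write_contacts(matrices, out / "contacts.txt")
    write_bed([s.interval for s in annot.sites], out / "ctcf.bed")
    genes_df = pd.DataFrame(
        [{"gene_id": g.gene_id, "chrom": g.chrom, "tss": g.tss,
          "strand": g.strand, "biotype": g.biotype,
          "transcription_factor": int(g.transcription_factor)}
         for g in annot.genes]).set_index("gene_id")
    write_table(genes_df, out / "genes.tsv")
    done(["contacts.txt", "ctcf.bed", "genes.tsv"])

    # --- domain calling ----------------------------------------------------
    done = _stage("domains")
    chrom = cfg.chrom_lengths[0][0]
    domains, dsum = call_domains(matrices[chrom], annot.sites,
                                 DomainCallParams())
    recovery = score_domain_recovery(domains, planted, cfg.bin_size)
    classify_domains(domains, list(annot.genes))
    _domains_frame(domains).to_csv(out / "domains.tsv", sep="\t", index=False)
    done(["domains.tsv"])
    summary["domains"] = {**dsum, **recovery}

    # --- TIG permutation test ----------------------------------------------
    done = _stage("permutation")
    perm = permutation_enrichment(domains, list(annot.genes), annot.genome,
                                  mode="domains", n_perm=n_perm, seed=seed)
    pd.DataFrame({"null_single_count": perm.null}).to_csv(
        out / "permutation_null.tsv", sep="\t", index=False)
    done(["permutation_null.tsv"])
    summary["permutation"] = {"observed": perm.observed, "p": perm.p_value}

    # --- virtual 4C ---------------------------------------------------------
    done = _stage("virtual4c")
    wide = [(i, d) for i, d in enumerate(domains)
            if d.length > 2 * flank_bins * cfg.bin_size]
    profiles = [boundary_profile(matrices[chrom], d, flank_bins, i)
                for i, d in wide]
    agg = aggregate_profiles([p for p in profiles if p is not None], "called")
    prof_df = pd.DataFrame({"left_mean": agg.left_mean, "left_se": agg.left_se,
                            "right_mean": agg.right_mean,
                            "right_se": agg.right_se})
    prof_df.to_csv(out / "v4c_profile.tsv", sep="\t", index=False)
    done(["v4c_profile.tsv"])
    center = agg.left_mean[flank_bins]
    flankm = np.nanmean(np.r_[agg.left_mean[:5], agg.left_mean[-5:]])
    summary["virtual4c"] = {"center_mean": float(center),
                            "center_flank_ratio": float(center / flankm)}

    # --- constitutive domains ----------------------------------------------
    done = _stage("constitutive")
    per_sample, truth_shared = simulate_multisample_domains(cfg)
    loops_by_sample = {s: [Loop(r.left, r.right) for r in recs]
                       for s, recs in per_sample.items()}
    union, _samples = constitutive_domains(loops_by_sample)
    const = [d for d in union if d.constitutive]
    _domains_frame(union).to_csv(out / "constitutive.tsv", sep="\t", index=False)
    done(["constitutive.tsv"])
    summary["constitutive"] = {
        "n_union": len(union), "n_constitutive": len(const),
        "jaccard_vs_truth": jaccard_domains(const, truth_shared)}

    # --- specificity --------------------------------------------------------
    done = _stage("specificity")
    tig_ids = [g.gene_id for g in annot.genes if g.transcription_factor]
    bg_ids = [g.gene_id for g in annot.genes if not g.transcription_factor]
    expr, truth_specific, _active = simulate_expression(
        cfg, specific_ids=tig_ids, background_ids=bg_ids)
    calls = call_specific_regulators(expr)
    called = {c.gene for c in calls if c.specific}
    prec, rec = precision_recall(called, truth_specific)
    pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
        out / "specificity.tsv", sep="\t", index=False)
    done(["specificity.tsv"])
    summary["specificity"] = {"n_called": len(called), "precision": prec,
                              "recall": rec}

    # --- boundary features --------------------------------------------------
    done = _stage("features")
    rng = cfg.rng(900)
    motifs = random_motifs(annot.genome, 400, cfg.motif_length, rng)
    boundary_m, other_m = motifs[:200], motifs[200:]
    gene_spans = {}
    for t in annot.single_gene_loops:
        pl = cfg.planted_loops[t]
        lo, hi = _loop_span(cfg, pl)
        gid = next((g.gene_id for g in annot.genes
                    if g.chrom == pl.chrom and lo <= g.tss < hi), None)
        if gid is not None:
            gene_spans[gid] = GenomicInterval(pl.chrom, lo, hi)
    tracks = simulate_tracks_and_variants(cfg, boundary_m, other_m,
                                          expression=expr,
                                          gene_spans=gene_spans)
    cons_p = compare_motif_conservation(
        {"boundary": boundary_m, "nonboundary": other_m}, tracks.conservation,
        flank_bp=cfg.track_flank_bp)
    vd_b = variant_density(boundary_m, tracks.variants)
    vd_o = variant_density(other_m, tracks.variants)
    pd.concat([vd_b.assign(group="boundary"),
               vd_o.assign(group="nonboundary")]).to_csv(
        out / "variant_density.tsv", sep="\t", index=False)
    done(["variant_density.tsv"])
    depletion = ((vd_b["common"].mean() + vd_b["rare"].mean())
                 / (vd_o["common"].mean() + vd_o["rare"].mean()))
    summary["features"] = {
        "conservation_p": float(cons_p["p_value"].iloc[0]),
        "variant_depletion_ratio": float(depletion)}

    # --- co-activation ------------------------------------------------------
    done = _stage("coactivation")
    truth_dom = planted_truth_domains(cfg)
    classify_domains(truth_dom, list(annot.genes))
    for d in truth_dom:
        d.constitutive = True
    norm = filter_active(normalize_enhancer_signal(tracks.enhancer_signal,
                                                   tracks.library_sizes))
    r_within = coactivation_correlation(norm, tracks.enhancer_intervals,
                                        truth_dom, list(annot.genes), expr,
                                        mode="within")
    r_cross = coactivation_correlation(norm, tracks.enhancer_intervals,
                                       truth_dom, list(annot.genes), expr,
                                       mode="cross")
    pd.DataFrame({"r_within": r_within, "r_cross": r_cross}).to_csv(
        out / "coactivation.tsv", sep="\t")
    done(["coactivation.tsv"])
    summary["coactivation"] = {
        "median_r_within": float(r_within.median()),
        "median_r_cross": float(r_cross.median()),
        "rank_sum_p": compare_coactivation(r_within, r_cross)}

    manifest["summary"] = summary
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return summary
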