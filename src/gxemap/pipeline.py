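"""End-to-end pipeline: simulate -> screen -> pools -> BSA -> HMM -> scan.

One :func:`run_pipeline` call simulates both backcrosses of the focal rough
recombinant, screens segregants for the rough phenotype, classifies them into
temperature-sensitivity classes from replicate colony scores, maps each class
by pooled sequencing, genotypes the HS individuals at low coverage with the
HMM, scans for genotypic heterogeneity, and dissects any significant pairs by
partitioning on the focal region.  All artifacts are written as the TSV/JSON
dialects of :mod:`gxemap.io`, and a summary JSON records the configuration,
the seed, and an evaluation block against the simulation truth record.

A fixed seed makes the whole run — including the summary bytes — reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from . import io as gio
from .bsa import BulkSegregantScan
from .genome import build_default_map, default_cross_design
from .hmm import carries_wildtype_ira2, coverage_filter, genotype_hmm, genotype_matrix
from .phenotypes import PhenotypeRecord, classified_fraction, classify_record
from .rules import RuleSet
from .scan import HeterogeneityScan
from .simulate import (
    simulate_individual_reads,
    simulate_panel,
    simulate_phenotype_scores,
    simulate_pool_counts,
)

CLASSES = ("HS", "MS", "NS")


class ConfigError(ValueError):
    """Invalid pipeline configuration; lists every offending field."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration: " + "; ".join(self.problems))


@dataclass
class PipelineConfig:
    """Every numeric setting of the pipeline, with desk-scale defaults."""

    seed: int = 0
    # map / cross
    snp_spacing: int = 800
    map_scale: float = 3300.0
    backcrosses: tuple = ("BY", "3S")
    # screen & phenotyping
    screen_temperature: int = 21
    n_collected: int = 120
    replicates: int = 3
    score_noise: float = 0.0
    # pooled sequencing
    pool_size: int = 100
    pool_depth: float = 150.0
    pool_error_rate: float = 0.005
    # individual sequencing + HMM
    individual_coverage: float = 1.2
    read_error_rate: float = 0.005
    hmm_error_rate: float = 0.005
    posterior_min: float = 0.9
    min_coverage: float = 1.02
    # locus calling
    lod_threshold: float = 5.0
    min_span: int = 20000
    lod_drop: float = 2.0
    smoothing_window: int = 25
    # heterogeneity scan
    q_threshold: float = 0.01
    telomere_margin: int = 20000
    freq_low: float = 0.10
    freq_high: float = 0.90
    ruleset_path: str | None = None

    def validate(self):
        problems = []
        positive = [
            "snp_spacing", "map_scale", "n_collected", "replicates", "pool_size",
            "pool_depth", "lod_threshold", "min_span", "lod_drop", "smoothing_window",
            "q_threshold", "telomere_margin", "min_coverage",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be positive (got {getattr(self, name)})")
        for name in ("pool_error_rate", "read_error_rate", "hmm_error_rate", "score_noise"):
            v = getattr(self, name)
            if not 0 <= v < 0.5 and name != "score_noise":
                problems.append(f"{name} must be in [0, 0.5) (got {v})")
            if name == "score_noise" and not 0 <= v <= 1:
                problems.append(f"{name} must be in [0, 1] (got {v})")
        if self.individual_coverage < 0:
            problems.append("individual_coverage must be >= 0")
        if self.screen_temperature not in (21, 30, 37):
            problems.append(f"screen_temperature must be one of 21/30/37 (got {self.screen_temperature})")
        if self.smoothing_window % 2 == 0:
            problems.append("smoothing_window must be odd")
        if not 0 <= self.freq_low < self.freq_high <= 1:
            problems.append("freq_low/freq_high must satisfy 0 <= low < high <= 1")
        if not 0.5 <= self.posterior_min <= 1:
            problems.append("posterior_min must be in [0.5, 1]")
        for bc in self.backcrosses:
            if bc not in ("BY", "3S"):
                problems.append(f"unknown backcross {bc!r}")
        if problems:
            raise ConfigError(problems)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError([f"unknown config key {k!r}" for k in sorted(unknown)])
        if "backcrosses" in doc:
            doc["backcrosses"] = tuple(doc["backcrosses"])
        return cls(**doc)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    return x


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full pipeline and return (and write) the summary."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    ruleset = RuleSet.default() if config.ruleset_path is None else RuleSet.from_json(
        Path(config.ruleset_path).read_text()
    )
    gmap = build_default_map(config.snp_spacing, config.map_scale)
    gio.write_genome_map(gmap, outdir / "snp_map.tsv", outdir / "chromosomes.tsv")
    (outdir / "ruleset.json").write_text(ruleset.to_json() + "\n")

    summary = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {k: _jsonable(v) if not isinstance(v, tuple) else list(v) for k, v in asdict(config).items()},
        "backcrosses": {},
    }
    union_loci = set()

    for bc in config.backcrosses:
        bdir = outdir / f"backcross_{bc}"
        bdir.mkdir(exist_ok=True)
        design = default_cross_design(gmap, bc)
        gio.write_cross_design(design, bdir / "design.tsv")

        panel = simulate_panel(design, ruleset, config.n_collected, config.screen_temperature, rng)
        panel.ids = [f"{bc}-{i:04d}" for i in range(panel.n)]
        truth = panel.truth_record(seed=config.seed)
        gio.write_json(truth, bdir / "truth.json")

        # replicate colony scores -> class calls
        records = [
            PhenotypeRecord(
                panel.ids[i],
                simulate_phenotype_scores(panel.classes[i], rng, config.replicates, config.score_noise),
            )
            for i in range(panel.n)
        ]
        gio.write_phenotypes(records, bdir / "phenotypes.tsv")
        calls = [classify_record(r) for r in records]
        gio.write_class_calls(calls, bdir / "class_calls.tsv")
        label_of = {c.individual: c.label for c in calls}

        causal = {
            loc["name"]: (loc["chromosome"], loc["position"] - 1) for loc in truth["causal_loci"]
        }
        bc_summary = {
            "n_examined": panel.n_examined,
            "n_collected": panel.n,
            "classified_fraction": round(classified_fraction(calls), 4),
            "class_counts": {
                cls: sum(1 for c in calls if c.label == cls) for cls in CLASSES + ("unclassified",)
            },
            "pools": {},
        }

        # --- bulk segregant mapping per class
        members_by_class = {
            cls: [i for i in range(panel.n) if label_of[panel.ids[i]] == cls][: config.pool_size]
            for cls in CLASSES
        }
        for cls in CLASSES:
            members = members_by_class[cls]
            if len(members) < 2:
                bc_summary["pools"][cls] = {"n_pooled": len(members), "loci": [], "note": "pool too small"}
                continue
            counts = simulate_pool_counts(
                panel.genomes[members], config.pool_depth, rng, config.pool_error_rate
            )
            gio.write_pool_counts(counts, gmap, bdir / f"pool_counts_{cls}.tsv")
            res = BulkSegregantScan(counts, gmap, design, n_individuals=len(members)).fit(
                window=config.smoothing_window,
                threshold=config.lod_threshold,
                min_span=config.min_span,
                drop=config.lod_drop,
            )
            gio.write_loci(res.loci, bdir / f"loci_{cls}.tsv")
            recovered = _loci_recovered(res.loci, causal)
            union_loci |= set(recovered)
            bc_summary["pools"][cls] = {
                "n_pooled": len(members),
                "loci": res.loci_frame().to_dict(orient="records"),
                "causal_recovered": recovered,
            }

        # --- HS class: individual genotyping + heterogeneity scan
        hs_members = [i for i in range(panel.n) if label_of[panel.ids[i]] == "HS"]
        scan_summary = {"n_hs": len(hs_members)}
        if len(hs_members) >= 4:
            obs = {
                panel.ids[i]: simulate_individual_reads(
                    panel.genomes[i], config.individual_coverage, rng, config.read_error_rate
                )
                for i in hs_members
            }
            gio.write_observations(obs, gmap, bdir / "observations.tsv")
            kept_ids, kept_calls = [], []
            n_low_cov = n_wildtype = 0
            for i in hs_members:
                ind = panel.ids[i]
                if not coverage_filter(obs[ind], config.min_coverage):
                    n_low_cov += 1
                    continue
                call = genotype_hmm(obs[ind], gmap, design, config.hmm_error_rate)
                if carries_wildtype_ira2(call, design):
                    n_wildtype += 1
                    continue
                kept_ids.append(ind)
                kept_calls.append(call)
            scan_summary.update({"n_low_coverage_excluded": n_low_cov, "n_wildtype_ira2_excluded": n_wildtype})
            if len(kept_calls) >= 4:
                matrix = genotype_matrix(kept_calls, design, config.posterior_min)
                snp_index = np.flatnonzero(design.read_segregating)
                gio.write_genotype_matrix(matrix, snp_index, kept_ids, gmap, bdir / "genotypes.tsv")
                res = HeterogeneityScan(matrix, gmap, snp_index).fit(
                    config.telomere_margin, config.q_threshold
                )
                gio.write_regions(res.regions, gmap, bdir / "regions.tsv")
                gio.write_pair_tests(res.tests, bdir / "pair_tests.tsv")
                scan_summary.update(
                    {
                        "n_regions": res.n_regions,
                        "n_tests": res.n_tests,
                        "significant_pairs": _pairs_records(res, gmap),
                    }
                )
                if len(res.significant):
                    focal = _most_connected_region(res)
                    focal_reg = res.regions[focal]
                    scan_summary["focal_region"] = {
                        "index": int(focal),
                        "chromosome": gmap.chrom_names[focal_reg.chromosome],
                        "start": focal_reg.start + 1,
                        "end": focal_reg.end,
                    }
                    try:
                        partition = res.partition(focal, config.smoothing_window, config.freq_low, config.freq_high)
                    except ValueError as exc:
                        scan_summary["partition"] = {"error": str(exc)}
                    else:
                        gio.write_partition_calls(partition, gmap, bdir / "partition_calls.tsv")
                        scan_summary["partition"] = {
                            group: {
                                "n_individuals": payload["n_individuals"],
                                "causal_called": _partition_recovered(payload["calls"], causal, gmap),
                            }
                            for group, payload in partition.items()
                        }
        bc_summary["heterogeneity_scan"] = scan_summary
        summary["backcrosses"][bc] = bc_summary

    summary["evaluation"] = {
        "union_causal_loci_detected": sorted(union_loci),
        "n_union_causal_loci": len(union_loci),
    }
    gio.write_json(summary, outdir / "summary.json")
    return summary


def _loci_recovered(calls, causal: dict) -> list:
    """Causal loci whose true position falls inside a call's support interval."""
    hit = []
    for name, (chrom, pos0) in causal.items():
        for call in calls:
            if call.chromosome == chrom and call.start <= pos0 < call.end:
                hit.append(name)
                break
    return sorted(hit)


def _partition_recovered(calls_df, causal: dict, gmap) -> list:
    hit = []
    for name, (chrom, pos0) in causal.items():
        for _, row in calls_df.iterrows():
            if gmap.chrom_names[int(row["chromosome"])] == chrom and row["start"] <= pos0 < row["end"]:
                hit.append(f"{name}^{row['allele']}")
                break
    return sorted(hit)


def _pairs_records(res, gmap) -> list:
    out = []
    for _, row in res.significant.iterrows():
        ra, rb = res.regions[int(row["region_a"])], res.regions[int(row["region_b"])]
        out.append(
            {
                "chrom_a": gmap.chrom_names[ra.chromosome],
                "chrom_b": gmap.chrom_names[rb.chromosome],
                "chi2": round(float(row["chi2"]), 4),
                "p": float(row["p"]),
                "q": float(row["q"]),
            }
        )
    return out


def _most_connected_region(res) -> int:
    """Region appearing in the most significant pairs (the partition anchor)."""
    from collections import Counter

    counts = Counter()
    for _, row in res.significant.iterrows():
        counts[int(row["region_a"])] += 1
        counts[int(row["region_b"])] += 1
    top = max(counts.values())
    candidates = sorted(r for r, c in counts.items() if c == top)
    return candidates[0]
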