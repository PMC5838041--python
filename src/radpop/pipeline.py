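"""End-to-end orchestration: filter -> thin -> statistics -> report.

A :class:`RunConfig` names the inputs and toggles each analysis stage;
:func:`run_pipeline` executes the stages in method order, writes every
stage's output under the run directory, and records a manifest with the
config hash and seeds so a run can be reproduced exactly.  Stages are
isolated: an error in one analysis is captured in the manifest and the
remaining independent stages still run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .distance import (
    average_by_locality,
    haversine_matrix,
    mantel_test,
    p_distance_matrix,
    DistanceMatrix,
)
from .dstat import RETENTION_LEVELS, dstat_analysis, dstat_table
from .filtering import (
    FilterConfig,
    apply_filters,
    flag_low_call_individuals,
    select_ebsp_loci,
    subset_no_missing,
    thin_one_snp_per_contig,
    write_ebsp_exports,
)
from .fst import allele_counts, reich_fst
from .io import PopulationMap, read_vcf, write_vcf
from .pca import genotype_pca


@dataclass
class RunConfig:
    vcf: str
    popmap: str
    out_dir: str
    seed: int = 0
    filter: FilterConfig = field(default_factory=FilterConfig)
    drop_low_call_individuals: bool = True
    low_call_fraction: float = 0.25
    outgroup: str | None = None
    fst_pairs: list[tuple[str, str]] = field(default_factory=list)
    dstat_topologies: list[tuple[str, str, str, str]] = field(default_factory=list)
    dstat_reps: int = 1000
    dstat_levels: tuple[float, ...] = RETENTION_LEVELS
    mantel: bool = False
    mantel_permutations: int = 999
    mantel_tail: str = "greater"
    geographic_matrix: str | None = None  # e.g. along-shore distances
    pca_axes: int = 0  # 0 = stage off
    ebsp: bool = False
    ebsp_n_loci: int = 50
    ebsp_snps_per_locus: int = 4
    ebsp_min_individuals: int | None = None
    ebsp_replicates: int = 3
    forward_read_length: int = 95

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        filt = FilterConfig(**raw.pop("filter", {}))
        if "fst_pairs" in raw:
            raw["fst_pairs"] = [tuple(p) for p in raw["fst_pairs"]]
        if "dstat_topologies" in raw:
            raw["dstat_topologies"] = [tuple(t) for t in raw["dstat_topologies"]]
        if "dstat_levels" in raw:
            raw["dstat_levels"] = tuple(raw["dstat_levels"])
        return cls(filter=filt, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["filter"] = dataclasses.asdict(self.filter)
        return d


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _focal_populations(popmap: PopulationMap, outgroup: str | None) -> list[str]:
    return [p for p in popmap.populations if p != outgroup]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Always runs: read, filter (report written), thin (thinned VCF
    written).  Optional stages: F_ST pairs, D-statistic topologies,
    Mantel tests (straight-line geography, plus a user-supplied
    distance matrix if given), PCA, EBSP locus export.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "errors": {},
    }

    dataset = read_vcf(config.vcf)
    popmap = PopulationMap.from_tsv(config.popmap)
    known = set(popmap.populations)
    for pair in config.fst_pairs:
        for p in pair:
            if p not in known:
                raise ValueError(f"population {p!r} not in popmap")

    filtered, report = apply_filters(dataset, config.filter)
    flagged = flag_low_call_individuals(report, config.low_call_fraction)
    if flagged and config.drop_low_call_individuals:
        keep = [s for s in filtered.sample_ids if s not in flagged]
        filtered = filtered.subset_samples(keep)
    report.to_json(out / "filter_report.json")
    (out / "filter_report.txt").write_text(report.to_text())
    manifest["stages"]["filter"] = {
        "sites_out": report.sites_out,
        "excluded_individuals": flagged,
    }

    thinned = thin_one_snp_per_contig(filtered)
    write_vcf(thinned, out / "thinned.vcf")
    manifest["stages"]["thin"] = {"sites_out": thinned.n_sites}

    counts = None
    if config.fst_pairs or config.dstat_topologies:
        counts = allele_counts(thinned, popmap)

    if config.fst_pairs:
        try:
            rows = []
            for p1, p2 in config.fst_pairs:
                r = reich_fst(counts, p1, p2)
                rows.append({"pop1": p1, "pop2": p2, **r.to_dict()})
            import pandas as pd

            df = pd.DataFrame(rows)
            df.to_csv(out / "fst.tsv", sep="\t", index=False)
            (out / "fst.json").write_text(json.dumps(rows, indent=2) + "\n")
            manifest["stages"]["fst"] = {"pairs": len(rows)}
        except Exception:
            manifest["errors"]["fst"] = traceback.format_exc()

    if config.dstat_topologies:
        try:
            results = [
                dstat_analysis(
                    counts, *topo,
                    levels=config.dstat_levels,
                    n_reps=config.dstat_reps,
                    seed=config.seed,
                )
                for topo in config.dstat_topologies
            ]
            dstat_table(results).to_csv(out / "dstat.tsv", sep="\t", index=False)
            (out / "dstat.json").write_text(
                json.dumps([r.to_dict() for r in results], indent=2) + "\n"
            )
            manifest["stages"]["dstat"] = {"topologies": len(results)}
        except Exception:
            manifest["errors"]["dstat"] = traceback.format_exc()

    if config.mantel:
        try:
            focal = _focal_populations(popmap, config.outgroup)
            focal_samples = [
                s for s in thinned.sample_ids
                if popmap.population_of(s) in focal
            ]
            gsub = thinned.subset_samples(focal_samples)
            pdist = average_by_locality(p_distance_matrix(gsub), popmap)
            pdist.to_tsv(out / "p_distance_localities.tsv")
            coords = popmap.locality_coords().loc[pdist.labels]
            geo = haversine_matrix(
                list(map(tuple, coords.to_numpy())), pdist.labels
            )
            geo.to_tsv(out / "geographic_km.tsv")
            tests = {}
            m = mantel_test(
                geo, pdist,
                n_permutations=config.mantel_permutations,
                tail=config.mantel_tail, seed=config.seed,
            )
            tests["straight_line"] = dataclasses.asdict(m)
            if config.geographic_matrix:
                user = DistanceMatrix.from_tsv(config.geographic_matrix)
                m2 = mantel_test(
                    user.reorder(pdist.labels), pdist,
                    n_permutations=config.mantel_permutations,
                    tail=config.mantel_tail, seed=config.seed,
                )
                tests["user_supplied"] = dataclasses.asdict(m2)
            (out / "mantel.json").write_text(json.dumps(tests, indent=2) + "\n")
            manifest["stages"]["mantel"] = {
                k: {"r": v["r_observed"], "p": v["p_value"]}
                for k, v in tests.items()
            }
        except Exception:
            manifest["errors"]["mantel"] = traceback.format_exc()

    if config.pca_axes > 0:
        try:
            focal = _focal_populations(popmap, config.outgroup)
            focal_samples = [
                s for s in thinned.sample_ids
                if popmap.population_of(s) in focal
            ]
            complete = subset_no_missing(thinned.subset_samples(focal_samples))
            pres = genotype_pca(complete, n_axes=config.pca_axes)
            pres.scores_frame().to_csv(out / "pca_scores.tsv", sep="\t")
            import pandas as pd

            pd.DataFrame(
                {
                    "axis": [f"PC{i+1}" for i in range(pres.n_axes)],
                    "variance_fraction": pres.variance_fraction,
                }
            ).to_csv(out / "pca_variance.tsv", sep="\t", index=False)
            manifest["stages"]["pca"] = {
                "n_sites": pres.n_sites,
                "variance_fraction": pres.variance_fraction.tolist(),
            }
        except Exception:
            manifest["errors"]["pca"] = traceback.format_exc()

    if config.ebsp:
        try:
            sel = select_ebsp_loci(
                filtered,
                n_loci=config.ebsp_n_loci,
                snps_per_locus=config.ebsp_snps_per_locus,
                min_individuals=config.ebsp_min_individuals,
                n_replicates=config.ebsp_replicates,
                seed=config.seed,
                forward_read_length=config.forward_read_length,
            )
            write_ebsp_exports(sel, out / "ebsp")
            manifest["stages"]["ebsp"] = {
                "candidates": len(sel.candidates),
                "replicates": [len(r) for r in sel.replicates],
            }
        except Exception:
            manifest["errors"]["ebsp"] = traceback.format_exc()

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
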