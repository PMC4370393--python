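"""Run the full analysis workflow from a single YAML configuration.

The pipeline takes a band matrix from disk (or simulates one), then runs the
enabled stages in dependency order: marker informativeness, within-population
diversity, AMOVA + pairwise Fst + gene flow, the LD screen, Nei distances
with UPGMA/PCoA/Mantel, the hierarchical Bayesian fits, and admixture
clustering with Evanno DeltaK. Every output table carries a provenance
header (package version, stage seed, parameters); one global seed
deterministically derives per-stage seeds so stages stay independent.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .admixture import assign_individuals, evanno_delta_k, fit_admixture
from .bayes import VARIANTS, compare_models, fit_hickory
from .core import BinaryMarkerMatrix, read_matrix
from .differentiation import amova, gene_flow, gst, ld_screen, pairwise_fst
from .distances import geographic_distances, mantel, nei_distance_matrix, pcoa, upgma
from .diversity import population_diversity
from .informativeness import primer_report
from .simulate import paper_like_dataset, simulate

__all__ = ["RunConfig", "run_pipeline"]

_ALL_STAGES = (
    "informativeness",
    "diversity",
    "amova",
    "pairwise_fst",
    "geneflow",
    "ld",
    "distance",
    "hickory",
    "structure",
)


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    input_path: str | None = None
    dialect: str = "csv"
    missing_code: str = "-9"
    simulate: dict | None = None            # used when input_path is None
    stages: list[str] = field(default_factory=lambda: list(_ALL_STAGES))
    seed: int = 0
    output_dir: str = "dompop_out"
    n_permutations: int = 1000
    mcmc: dict = field(default_factory=dict)      # burn_in/samples/thin
    structure: dict = field(default_factory=dict) # k_range/replicates/burn_in/reps
    assignment_threshold: float = 0.8
    coordinates: str | None = None          # CSV with population,longitude,latitude
    panel: str | None = None                # CSV with locus,primer columns

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.input_path is not None and not Path(self.input_path).exists():
            raise FileNotFoundError(f"input path {self.input_path!r} does not exist")
        if self.input_path is None and self.simulate is None:
            self.simulate = {}  # paper-like default
        kr = self.structure.get("k_range")
        if kr is not None and list(kr) != sorted(set(kr)):
            raise ValueError("structure.k_range must be strictly increasing")
        if self.coordinates is not None and not Path(self.coordinates).exists():
            raise FileNotFoundError(f"coordinates file {self.coordinates!r} missing")


def _stage_seed(global_seed: int, stage: str) -> int:
    # stable across processes (unlike hash())
    h = np.random.SeedSequence([global_seed, zlib.crc32(stage.encode())])
    return int(h.generate_state(1)[0] % (2**31))


def _header(stage: str, seed: int, params: dict) -> str:
    return (
        f"# dompop {__version__} | stage={stage} | seed={seed} | "
        f"params={json.dumps(params, sort_keys=True, default=str)}\n"
    )


def _write(df: pd.DataFrame, path: Path, stage: str, seed: int, params: dict) -> None:
    with open(path, "w") as fh:
        fh.write(_header(stage, seed, params))
        df.to_csv(fh, sep="\t", index=True)


def run_pipeline(config: RunConfig, log=print) -> dict:
    """Execute all enabled stages; returns a dict of in-memory results."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    if config.input_path is not None:
        matrix = read_matrix(config.input_path, config.dialect, config.missing_code)
        if config.panel is not None:
            pdf = pd.read_csv(config.panel)
            matrix.primer_of = dict(
                zip(pdf["locus"].astype(str), pdf["primer"].astype(str))
            )
    else:
        sim = dict(config.simulate or {})
        sim_seed = sim.pop("seed", _stage_seed(config.seed, "simulate"))
        if sim:
            matrix, truth = simulate(seed=sim_seed, **sim)
        else:
            matrix, truth = paper_like_dataset(seed=sim_seed)
        results["truth"] = truth
    results["matrix"] = matrix
    log(f"matrix: {matrix.n_individuals} individuals x {matrix.n_loci} loci, "
        f"{len(matrix.population_labels)} populations")

    def enabled(stage: str) -> bool:
        return stage in config.stages

    def timed(stage, fn):
        t0 = time.perf_counter()
        try:
            value = fn()
        except Exception as exc:  # surface the failing stage
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        log(f"stage {stage}: {time.perf_counter() - t0:.2f}s")
        return value

    if enabled("informativeness") and matrix.primer_of:
        seed = _stage_seed(config.seed, "informativeness")
        df = timed("informativeness", lambda: primer_report(matrix))
        _write(df.set_index("primer"), out / "informativeness.tsv",
               "informativeness", seed, {})
        results["informativeness"] = df

    if enabled("diversity"):
        seed = _stage_seed(config.seed, "diversity")
        df = timed("diversity", lambda: population_diversity(matrix))
        _write(df, out / "diversity.tsv", "diversity", seed, {})
        results["diversity"] = df

    if enabled("amova"):
        seed = _stage_seed(config.seed, "amova")
        res = timed("amova", lambda: amova(matrix, config.n_permutations, seed))
        df = pd.DataFrame(
            {
                "df": [res.df_among, res.df_within],
                "SSD": [res.ssd_among, res.ssd_within],
                "variance": [res.sigma2_among, res.sigma2_within],
                "percent": [res.percent_among, res.percent_within],
            },
            index=["among", "within"],
        )
        _write(df, out / "amova.tsv", "amova", seed,
               {"phi_st": res.phi_st, "p": res.p_value, "gst": gst(matrix)})
        results["amova"] = res

    if enabled("pairwise_fst"):
        seed = _stage_seed(config.seed, "pairwise_fst")
        fst, pvals = timed(
            "pairwise_fst", lambda: pairwise_fst(matrix, config.n_permutations, seed)
        )
        _write(pd.DataFrame(fst.values, index=fst.labels, columns=fst.labels),
               out / "pairwise_fst.tsv", "pairwise_fst", seed, {})
        results["pairwise_fst"] = fst

    if enabled("geneflow") and "amova" in results and results["amova"].defined:
        phi = results["amova"].phi_st
        if 0 < phi < 1:
            results["geneflow"] = gene_flow(phi)
            (out / "geneflow.txt").write_text(
                _header("geneflow", config.seed, {"fst": phi})
                + f"Nm\t{results['geneflow'].nm:.6f}\n"
            )

    if enabled("ld"):
        seed = _stage_seed(config.seed, "ld")
        res = timed("ld", lambda: ld_screen(matrix))
        (out / "ld_screen.txt").write_text(
            _header("ld", seed, {}) + "\n".join(f"{k}\t{v}" for k, v in res.items()) + "\n"
        )
        results["ld"] = res

    if enabled("distance"):
        seed = _stage_seed(config.seed, "distance")
        nei = timed("nei", lambda: nei_distance_matrix(matrix))
        _write(pd.DataFrame(nei.values, index=nei.labels, columns=nei.labels),
               out / "nei_distance.tsv", "distance", seed, {})
        tree = upgma(nei)
        (out / "upgma.nwk").write_text(tree.newick() + "\n")
        ord_res = pcoa(nei)
        _write(
            pd.DataFrame(
                ord_res.coordinates, index=ord_res.labels,
                columns=[f"axis{i+1}" for i in range(ord_res.coordinates.shape[1])],
            ),
            out / "pcoa.tsv", "pcoa", seed,
            {"percent_variance": np.round(ord_res.percent_variance, 4).tolist()},
        )
        results["nei"] = nei
        results["upgma"] = tree
        results["pcoa"] = ord_res
        if config.coordinates is not None:
            coords = pd.read_csv(config.coordinates)
            from .core import PopulationSite
            sites = [
                PopulationSite(name=r.population, longitude=float(r.longitude),
                               latitude=float(r.latitude))
                for r in coords.itertuples(index=False)
            ]
            geo = geographic_distances(sites)
            geo = geo.reorder(nei.labels)
            r, p = mantel(nei, geo, n_perm=config.n_permutations, seed=seed)
            results["mantel"] = (r, p)
            (out / "mantel.txt").write_text(
                _header("mantel", seed, {}) + f"r\t{r:.6f}\np\t{p:.6f}\n"
            )

    if enabled("hickory"):
        seed = _stage_seed(config.seed, "hickory")
        mcmc = {"burn_in": 50_000, "samples": 250_000, "thin": 50, **config.mcmc}
        fits = []
        for i, variant in enumerate(VARIANTS):
            fits.append(
                timed(f"hickory[{variant}]",
                      lambda v=variant, s=seed + i: fit_hickory(matrix, v, seed=s, **mcmc))
            )
        ranking = compare_models(fits)
        rows = []
        for fit in fits:
            for param, s in fit.summaries.items():
                rows.append({"variant": fit.variant, "parameter": param, **s,
                             "dic": fit.dic})
        _write(pd.DataFrame(rows).set_index(["variant", "parameter"]),
               out / "hickory.tsv", "hickory", seed, mcmc)
        results["hickory"] = fits
        results["hickory_ranking"] = ranking

    if enabled("structure"):
        seed = _stage_seed(config.seed, "structure")
        scfg = {"k_range": [1, 2, 3, 4], "replicates": 3,
                "burn_in": 10_000, "reps": 100_000, **config.structure}
        ln_probs: dict[int, list[float]] = {}
        runs: dict[int, list] = {}
        counter = 0
        for k in scfg["k_range"]:
            ln_probs[k] = []
            runs[k] = []
            for _ in range(scfg["replicates"]):
                res = timed(
                    f"structure[K={k}]",
                    lambda kk=k, s=seed + counter: fit_admixture(
                        matrix, kk, burn_in=scfg["burn_in"], reps=scfg["reps"], seed=s
                    ),
                )
                ln_probs[k].append(res.ln_prob)
                runs[k].append(res)
                counter += 1
        table, best_k = evanno_delta_k(ln_probs)
        _write(table.set_index("K"), out / "delta_k.tsv", "structure", seed, scfg)
        best = runs[best_k][int(np.argmax(ln_probs[best_k]))]
        assignments, summary = assign_individuals(best.q, config.assignment_threshold)
        qdf = pd.DataFrame(
            best.q, index=best.individual_ids,
            columns=[f"cluster{c+1}" for c in range(best.k)],
        )
        qdf["assignment"] = [
            a if a == "admixed" else f"cluster{a+1}" for a in assignments
        ]
        _write(qdf, out / "q_matrix.tsv", "structure", seed,
               {"K": best_k, "threshold": config.assignment_threshold})
        results["structure"] = {"delta_k": table, "optimal_k": best_k,
                                "best_run": best, "summary": summary}

    return results
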