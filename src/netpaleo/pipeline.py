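"""End-to-end orchestration: run every analysis stage on one dataset
and emit plain-TSV reports plus a run manifest.

Stage order follows the logic of the analysis: origin census first,
then the validation analyses (concerted presence, degree-vs-age,
gain/loss rates with the steady-state correction, co-evolution), then
gene-set construction, enrichment and the network-weight tests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__, io
from .coevolution import (
    DEFAULT_MIN_BRANCHES,
    DEFAULT_OMEGA_CUTOFF,
    clade_removal_scan,
    shared_selection_test,
)
from .enrichment import define_gene_sets, hypergeometric_enrichment
from .network_stats import (
    compare_degree_difference_sets,
    compare_degree_sets,
    constraint_assortativity_test,
    degree_assortativity_test,
)
from .origins import (
    concerted_presence_test,
    degree_age_correlation,
    gain_rate,
    loss_rate,
    origin_census,
    steady_state_correction,
)
from .phylogeny import (
    LOSS_CALIBRATION_BRANCHES,
    ORIGIN_CLASSES,
    BRANCHES,
    read_phylogeny,
)
from .synthetic import SimulationConfig, make_study_fixture

log = logging.getLogger(__name__)

DEFAULT_PARAMS: dict[str, Any] = {
    "omega_cutoff": DEFAULT_OMEGA_CUTOFF,
    "min_branches": DEFAULT_MIN_BRANCHES,
    "shared_thresholds": [1.0, 0.5],
    "adapt_threshold": 0.5,
    "n_null_coevolution": 1000,
    "n_null_concerted": 100,
    "n_null_degree_age": 100,
    "n_perm_constraint": 10000,
    "n_rewire": 1000,
    "n_swaps_per_edge": 10,
}

STAGES = (
    "origins",
    "concerted",
    "degree-age",
    "rates",
    "coevolve",
    "shared-selection",
    "gene-sets",
    "enrich",
    "degree-stats",
    "netweight",
)


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage tag."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _f(x: float) -> str:
    return format(float(x), ".6g")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def run_all(
    config: Mapping[str, Any],
    outdir,
    seed: int | None = None,
    skip: tuple[str, ...] = (),
) -> dict:
    """Run the full pipeline; returns (and writes) the run manifest.

    ``config`` either names input files under ``inputs`` or requests a
    synthetic study under ``simulate``; ``params`` overrides analysis
    defaults.  Any stage failure aborts with a stage-tagged error and
    partial outputs are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    params = dict(DEFAULT_PARAMS)
    params.update(config.get("params", {}))
    skip = tuple(skip) + tuple(config.get("skip", ()))
    for s in skip:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r} in skip list")

    manifest: dict[str, Any] = {
        "package_version": __version__,
        "seed": seed,
        "config": {k: v for k, v in config.items()},
        "params": params,
        "skipped_stages": sorted(skip),
        "stage_runtime_s": {},
        "inputs": {},
        "outputs": [],
    }
    t_all = time.perf_counter()

    # ---- inputs -----------------------------------------------------
    if "inputs" in config:
        paths = {k: Path(v) for k, v in config["inputs"].items()}
        network = io.read_network(paths["network"])
        presence = (
            io.read_presence_matrix(paths["presence"]) if "presence" in paths else None
        )
        phylo = (
            read_phylogeny(paths["tree"], paths.get("roles"))
            if "tree" in paths
            else None
        )
        branch_omega = (
            io.read_branch_omega(paths["branch_omega"])
            if "branch_omega" in paths
            else None
        )
        gene_omega = (
            io.read_gene_omega(paths["gene_omega"]) if "gene_omega" in paths else None
        )
        annotations = (
            io.read_annotations(paths["annotations"])
            if "annotations" in paths
            else {}
        )
        manifest["inputs"] = {k: _sha256(p) for k, p in paths.items()}
    else:
        sim_cfg = SimulationConfig(**config.get("simulate", {}))
        fixture_dir = outdir / "fixture"
        ds = make_study_fixture(fixture_dir, sim_cfg, seed=seed)
        network, presence, phylo = ds.network, ds.presence, ds.phylo
        branch_omega, gene_omega = ds.branch_omega, ds.gene_omega
        annotations = ds.annotations
        manifest["inputs"] = {
            p.name: _sha256(p) for p in sorted(fixture_dir.iterdir())
        }

    outputs: list[Path] = []

    def stage(name):
        def deco(fn):
            if name in skip:
                log.info("[%s] skipped", name)
                return None
            t0 = time.perf_counter()
            log.info("[%s] start", name)
            try:
                result = fn()
            except Exception as exc:  # tag and re-raise
                raise PipelineError(f"[{name}] {exc}") from exc
            manifest["stage_runtime_s"][name] = round(time.perf_counter() - t0, 3)
            return result

        return deco

    # ---- origins ----------------------------------------------------
    @stage("origins")
    def census():
        if presence is None or phylo is None:
            raise ValueError("a presence matrix and tree are required")
        c = origin_census(network, presence, phylo)
        with open(outdir / "origin_assignments.tsv", "w") as fh:
            fh.write("gene_a\tgene_b\torigin_class\n")
            for (a, b), cls in sorted(c.assignments.items()):
                fh.write(f"{a}\t{b}\t{cls}\n")
        with open(outdir / "origin_census.tsv", "w") as fh:
            fh.write("origin_class\tn_pairs\tnode_presence_fraction\n")
            for cls in ORIGIN_CLASSES:
                fh.write(
                    f"{cls}\t{c.counts.get(cls, 0)}\t{_f(c.node_fraction(cls))}\n"
                )
        outputs.extend([outdir / "origin_assignments.tsv", outdir / "origin_census.tsv"])
        return c

    @stage("concerted")
    def concerted():
        r = concerted_presence_test(
            network, presence, n_null=params["n_null_concerted"], seed=seed
        )
        with open(outdir / "concerted_presence.tsv", "w") as fh:
            fh.write(
                "species\tboth_present\tfirst_absent\tsecond_absent\tboth_absent\n"
            )
            for sp, counts in r.per_species.items():
                fh.write(
                    f"{sp}\t{counts[4]}\t{counts[2]}\t{counts[1]}\t{counts[0]}\n"
                )
            fh.write(
                f"# pooled concordant observed={r.pooled.observed:.0f} "
                f"null_mean={_f(r.pooled.null_mean)} p={r.pooled.p_label}\n"
            )
        outputs.append(outdir / "concerted_presence.tsv")
        return r

    @stage("degree-age")
    def degree_age():
        r = degree_age_correlation(
            network, presence, phylo, n_null=params["n_null_degree_age"], seed=seed
        )
        with open(outdir / "degree_age.tsv", "w") as fh:
            fh.write("origin_class\tbranch_age_ks\tmean_degree\n")
            for cls in ORIGIN_CLASSES:
                if cls in r.mean_degree:
                    fh.write(
                        f"{cls}\t{_f(r.branch_age[cls])}\t{_f(r.mean_degree[cls])}\n"
                    )
            fh.write(
                f"# pearson_r={_f(r.perm.observed)} p={r.perm.p_label} "
                f"direction={r.perm.direction} n_null={r.perm.n_replicates}\n"
            )
        outputs.append(outdir / "degree_age.tsv")
        return r

    @stage("rates")
    def rates():
        if census is None:
            raise ValueError("origins stage was skipped")
        rows = []
        for br in LOSS_CALIBRATION_BRANCHES:
            try:
                r = loss_rate(br, network, presence, phylo)
                rows.append(("loss", br, r.events, r.exposure, r.ks, r.rate))
            except ValueError as exc:
                log.warning("[rates] loss on %s unavailable: %s", br, exc)
        gains = {}
        for cls in ORIGIN_CLASSES:
            try:
                r = gain_rate(cls, census, phylo)
                gains[cls] = r.rate
                rows.append(("gain", cls, r.events, r.exposure, r.ks, r.rate))
            except ValueError as exc:
                log.warning("[rates] gain on %s unavailable: %s", cls, exc)
        # correction uses the lowest available gain rate off the youngest
        # classes, preferring the shared primate stem as the calibration
        g = gains.get("primates")
        if g is None and gains:
            g = min(gains.values())
        corr = steady_state_correction(g or 0.0, census, phylo)
        with open(outdir / "rates.tsv", "w") as fh:
            fh.write("kind\tbranch\tevents\texposure\tks\trate\n")
            for kind, br, ev, ex, ks, rate in rows:
                fh.write(f"{kind}\t{br}\t{ev}\t{ex}\t{_f(ks)}\t{_f(rate)}\n")
            fh.write(
                f"# raw_root_fraction={_f(corr.raw_root_fraction)} "
                f"corrected_root_fraction={_f(corr.corrected_root_fraction)} "
                f"gain_rate={_f(corr.gain_rate)} note={corr.note}\n"
            )
        outputs.append(outdir / "rates.tsv")
        return rows, corr

    @stage("coevolve")
    def coevolve():
        if branch_omega is None:
            raise ValueError("no branch-omega table provided")
        rows = clade_removal_scan(
            network,
            branch_omega,
            n_null=params["n_null_coevolution"],
            cutoff=params["omega_cutoff"],
            min_branches=params["min_branches"],
            seed=seed,
        )
        with open(outdir / "coevolution.tsv", "w") as fh:
            fh.write(
                "clade_removed\tn_ppis\tp\tmean_rho\tmean_of_means\tdifference\n"
            )
            for r in rows:
                fh.write(
                    f"{r.clade}\t{r.n_ppis}\t{r.p_label}\t{_f(r.mean_rho)}\t"
                    f"{_f(r.mean_of_means)}\t{_f(r.difference)}\n"
                )
        outputs.append(outdir / "coevolution.tsv")
        return rows

    @stage("shared-selection")
    def shared():
        if branch_omega is None:
            raise ValueError("no branch-omega table provided")
        results = []
        with open(outdir / "shared_selection.tsv", "w") as fh:
            fh.write(
                "branch\tthreshold\tn_pairs\tobserved\texpected\tchi2\tp\tnote\n"
            )
            for thr in params["shared_thresholds"]:
                for br in BRANCHES:
                    r = shared_selection_test(
                        network, branch_omega, br, threshold=thr
                    )
                    results.append(r)
                    chi2 = _f(r.chi2) if r.chi2 is not None else "NA"
                    p = _f(r.p) if r.p is not None else "NA"
                    fh.write(
                        f"{br}\t{thr}\t{r.n_pairs}\t{r.observed}\t"
                        f"{_f(r.expected)}\t{chi2}\t{p}\t{r.note}\n"
                    )
        outputs.append(outdir / "shared_selection.tsv")
        return results

    @stage("gene-sets")
    def gene_sets():
        if census is None:
            raise ValueError("origins stage was skipped")
        return define_gene_sets(
            census.assignments,
            network,
            branch_table=branch_omega,
            adapt_threshold=params["adapt_threshold"],
        )

    @stage("enrich")
    def enrich():
        if gene_sets is None:
            raise ValueError("gene-sets stage was skipped")
        if not annotations:
            raise ValueError("no annotation table available")
        for set_id, gs in gene_sets.items():
            path = outdir / f"enrichment_{set_id}.tsv"
            with open(path, "w") as fh:
                fh.write(
                    "set\tterm\tobserved\texpected\tfold_excess\tp_raw\t"
                    "p_bonferroni\tdirection\n"
                )
                if not gs.members:
                    fh.write(f"# {set_id}: empty study set, no test\n")
                else:
                    for row in hypergeometric_enrichment(gs, annotations):
                        fh.write(
                            f"{set_id}\t{row.term}\t{row.observed}\t"
                            f"{_f(row.expected)}\t{_f(row.fold_excess)}\t"
                            f"{_f(row.p_raw)}\t{_f(row.p_adjusted)}\t{row.direction}\n"
                        )
            outputs.append(path)
        return True

    @stage("degree-stats")
    def degree_stats():
        if gene_sets is None or census is None:
            raise ValueError("a required upstream stage was skipped")
        lines = ["comparison\tn_a\tn_b\tk_mean_a\tk_mean_b\tk_max_a\tk_max_b\tp"]
        for set_id in ("PrimPresI", "PrimUniqI"):
            gs = gene_sets[set_id]
            if gs.members and gs.complement:
                c = compare_degree_sets(
                    sorted(gs.members), sorted(gs.complement), network
                )
                lines.append(
                    f"{set_id}_vs_rest\t{c.n[0]}\t{c.n[1]}\t{_f(c.k_mean[0])}\t"
                    f"{_f(c.k_mean[1])}\t{c.k_max[0]}\t{c.k_max[1]}\t{_f(c.p)}"
                )
        prim = [
            p
            for p, cls in census.assignments.items()
            if cls in ("primates", "human-chimp", "human")
        ]
        rest = [
            p
            for p, cls in census.assignments.items()
            if cls not in ("primates", "human-chimp", "human")
        ]
        if prim and rest:
            d = compare_degree_difference_sets(prim, rest, network)
            lines.append(
                f"dk_primate_vs_rest\t{d.n[0]}\t{d.n[1]}\t{_f(d.mean_dk[0])}\t"
                f"{_f(d.mean_dk[1])}\t{d.max_dk[0]}\t{d.max_dk[1]}\t{_f(d.p)}"
            )
        (outdir / "degree_stats.tsv").write_text("\n".join(lines) + "\n")
        outputs.append(outdir / "degree_stats.tsv")
        return lines

    @stage("netweight")
    def netweight():
        if gene_omega is None:
            raise ValueError("no gene-omega table provided")
        rows = []
        w = constraint_assortativity_test(
            network, gene_omega, n_perm=params["n_perm_constraint"], seed=seed
        )
        rows.append(("omega-difference", w))
        d = degree_assortativity_test(
            network,
            n_rewire=params["n_rewire"],
            n_swaps_per_edge=params["n_swaps_per_edge"],
            seed=seed,
        )
        rows.append(("degree-difference", d))
        with open(outdir / "network_weight.tsv", "w") as fh:
            fh.write(
                "statistic\tobserved_w\tnull_mean\tnull_sd\tp\tdirection\t"
                "n_replicates\tseed\n"
            )
            for name, r in rows:
                fh.write(
                    f"{name}\t{_f(r.observed)}\t{_f(r.perm.null_mean)}\t"
                    f"{_f(r.perm.null_sd)}\t{r.perm.p_label}\t{r.perm.direction}\t"
                    f"{r.perm.n_replicates}\t{seed}\n"
                )
        outputs.append(outdir / "network_weight.tsv")
        return rows

    # ---- summary + manifest ----------------------------------------
    summary = [
        f"netpaleo {__version__} run (seed {seed})",
        f"network: {network.n_nodes} genes, {network.n_edges} interactions",
    ]
    if census is not None:
        summary.append(f"root presence fraction: {_f(census.node_fraction('root'))}")
    if rates is not None:
        _, corr = rates
        summary.append(
            f"corrected root fraction: {_f(corr.corrected_root_fraction)}"
        )
    if coevolve is not None:
        full = coevolve[0]
        summary.append(
            f"mean mirrortree rho: {_f(full.mean_rho)} "
            f"(null {_f(full.mean_of_means)}, p {full.p_label})"
        )
    if netweight is not None:
        summary.append(
            "network weight (|d-omega|): "
            f"{_f(netweight[0][1].observed)} vs null "
            f"{_f(netweight[0][1].perm.null_mean)} (p {netweight[0][1].perm.p_label})"
        )
    (outdir / "summary.txt").write_text("\n".join(summary) + "\n")
    outputs.append(outdir / "summary.txt")

    manifest["outputs"] = [
        {"file": p.name, "sha256": _sha256(p)} for p in outputs
    ]
    manifest["total_runtime_s"] = round(time.perf_counter() - t_all, 3)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
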