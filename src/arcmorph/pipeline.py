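"""Config-driven orchestration of the full analysis.

One element at a time: GPA (with sliding/symmetrization as configured), PCA
and dimensionality reduction, then for every configured pair of groups the
six-block comparison battery (size, shape, form, allometries, size variance,
shape variance) plus balanced cross-validation summaries, multiple-comparison
correction across the element's battery, a neighbour-joining phenogram over
all groups, and discriminant-axis shape endpoints.  Reports embed enough
provenance (package version, config hash, seeds, PC counts, estimator and
correction names) to re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    CrossValidationSummary,
    balanced_cv_summary,
    discriminant_shape_endpoints,
    mahalanobis_matrix,
)
from .haplotypes import (
    build_counts,
    fst_permutation_test,
    subclade_frequency_table,
)
from .io import MorphDataset, SliderScheme, SymmetryScheme, join_metadata
from .shapespace import pca, select_pc_count, to_form_matrix
from .stats import (
    TestResult,
    adjust_pvalues,
    fligner_killeen_test,
    mancova_allometry_test,
    manova_test,
    procrustes_variance_test,
    wilcoxon_size_test,
)
from .superimpose import GPAResult, gpa
from .trees import nj_tree

logger = logging.getLogger(__name__)

BLOCK_ORDER = ("size", "shape", "form", "allometries", "size_variance", "shape_variance")


@dataclass
class AnalysisParams:
    """Tunable knobs of the comparison pipeline, all overridable from config."""

    variance_threshold: float = 0.90
    n_cv_replicates: int = 100
    n_perm: int = 10000
    correction: str = "benjamini-hochberg"
    alpha: float = 0.05
    magnitude_sd: float = 3.0
    cv_size: bool = True
    recompute_pca_per_replicate: bool = False
    seed: int = 0


@dataclass
class PairwiseComparison:
    """One Table-style row block: all tests and CV summaries for two groups."""

    element: str
    group_a: str
    group_b: str
    blocks: dict[str, TestResult]
    cv: dict[str, CrossValidationSummary]
    n_pcs: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "element": self.element,
            "group_a": self.group_a,
            "group_b": self.group_b,
            "blocks": {k: v.to_dict() for k, v in self.blocks.items()},
            "cv": {k: v.to_dict() for k, v in self.cv.items()},
            "n_pcs": self.n_pcs,
        }


@dataclass
class ElementReport:
    element: str
    comparisons: list[PairwiseComparison]
    nj_newick: str
    group_counts: dict[str, int]
    gpa_iterations: int
    gpa_converged: bool
    endpoints: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "element": self.element,
            "group_counts": self.group_counts,
            "gpa_iterations": self.gpa_iterations,
            "gpa_converged": self.gpa_converged,
            "nj_newick": self.nj_newick,
            "comparisons": [c.to_dict() for c in self.comparisons],
            "endpoints": self.endpoints,
        }


def _spawn_seed(base: int, *keys: str) -> int:
    """Deterministic child seed from a base seed and string keys."""
    h = hashlib.sha256(("|".join(map(str, (base,) + keys))).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _pair_battery(
    aligned: GPAResult,
    labels: list[str],
    group_a: str,
    group_b: str,
    params: AnalysisParams,
    element: str,
) -> PairwiseComparison:
    lab_arr = np.asarray(labels)
    mask = (lab_arr == group_a) | (lab_arr == group_b)
    sub_labels = lab_arr[mask]
    flat = aligned.flat[mask]
    log_sizes = aligned.log_sizes[mask]
    n_a = int(np.sum(sub_labels == group_a))
    n_b = int(np.sum(sub_labels == group_b))
    sizes_pair = [n_a, n_b]

    shape_space = pca(flat)
    n_pcs_shape = select_pc_count(shape_space, sizes_pair, params.variance_threshold)
    shape_scores = shape_space.scores[:, :n_pcs_shape]

    form = np.hstack([flat, log_sizes[:, None]])
    form_space = pca(form)
    n_pcs_form = select_pc_count(form_space, sizes_pair, params.variance_threshold)
    form_scores = form_space.scores[:, :n_pcs_form]

    label_pair = (group_a, group_b)
    blocks: dict[str, TestResult] = {}
    blocks["size"] = wilcoxon_size_test(
        log_sizes[sub_labels == group_a], log_sizes[sub_labels == group_b], label_pair
    )
    blocks["shape"] = manova_test(shape_scores, sub_labels)
    blocks["form"] = manova_test(form_scores, sub_labels)
    blocks["allometries"] = mancova_allometry_test(shape_scores, log_sizes, sub_labels)
    blocks["size_variance"] = fligner_killeen_test(
        {group_a: log_sizes[sub_labels == group_a],
         group_b: log_sizes[sub_labels == group_b]}
    )
    blocks["shape_variance"] = procrustes_variance_test(
        flat, sub_labels, n_perm=params.n_perm,
        seed=_spawn_seed(params.seed, element, group_a, group_b, "dvar"),
    )

    cv: dict[str, CrossValidationSummary] = {}
    if params.cv_size:
        cv["size"] = balanced_cv_summary(
            log_sizes[:, None], sub_labels, params.n_cv_replicates,
            seed=_spawn_seed(params.seed, element, group_a, group_b, "cv_size"),
            n_pcs_used=1,
        )
    cv["shape"] = balanced_cv_summary(
        shape_scores, sub_labels, params.n_cv_replicates,
        seed=_spawn_seed(params.seed, element, group_a, group_b, "cv_shape"),
        n_pcs_used=n_pcs_shape,
    )
    cv["form"] = balanced_cv_summary(
        form_scores, sub_labels, params.n_cv_replicates,
        seed=_spawn_seed(params.seed, element, group_a, group_b, "cv_form"),
        n_pcs_used=n_pcs_form,
    )
    return PairwiseComparison(
        element=element, group_a=group_a, group_b=group_b,
        blocks=blocks, cv=cv,
        n_pcs={"shape": n_pcs_shape, "form": n_pcs_form},
    )


def analyze_element(
    dataset: MorphDataset,
    comparisons: list[tuple[str, str]],
    params: AnalysisParams | None = None,
    sliders: SliderScheme | None = None,
    symmetry: SymmetryScheme | None = None,
) -> ElementReport:
    """Run the full comparison battery for one skeletal element.

    Errors in one pairwise comparison are logged and that comparison is
    dropped; the remaining pairs still run.  Adjusted p-values are computed
    across all blocks of the element's battery.
    """
    params = params or AnalysisParams()
    aligned = gpa(dataset.configs, sliders=sliders, symmetry=symmetry)
    labels = dataset.labels

    results: list[PairwiseComparison] = []
    for group_a, group_b in comparisons:
        try:
            results.append(
                _pair_battery(aligned, labels, group_a, group_b, params, dataset.element)
            )
        except Exception:
            logger.exception(
                "comparison %s vs %s failed for element %s; skipping",
                group_a, group_b, dataset.element,
            )

    # multiple-comparison correction across all blocks of this element table
    flat_results = [(c, name) for c in results for name in BLOCK_ORDER]
    raw = [c.blocks[name].p_value for c, name in flat_results]
    if raw:
        adjusted = adjust_pvalues(raw, method=params.correction)
        for (c, name), adj in zip(flat_results, adjusted):
            c.blocks[name].p_adjusted = float(adj)

    # NJ phenogram over all groups with >= 2 specimens
    lab_arr = np.asarray(labels)
    counts = {g: int(np.sum(lab_arr == g)) for g in sorted(set(labels))}
    tree = ""
    nj_groups = [g for g, n in counts.items() if n >= 2]
    if len(nj_groups) >= 3:
        nj_mask = np.isin(lab_arr, nj_groups)
        space = pca(aligned.flat[nj_mask])
        n_pcs = select_pc_count(space, [counts[g] for g in nj_groups],
                                params.variance_threshold)
        dist = mahalanobis_matrix(space.scores[:, :n_pcs], lab_arr[nj_mask])
        tree = nj_tree(dist)

    endpoints: dict[str, dict] = {}
    for c in results:
        pair_mask = np.isin(lab_arr, [c.group_a, c.group_b])
        try:
            pair_shapes = aligned.shapes[pair_mask]
            ep = discriminant_shape_endpoints(
                pair_shapes, lab_arr[pair_mask],
                magnitude_sd=params.magnitude_sd,
                variance_threshold=params.variance_threshold,
            )
            endpoints[f"{c.group_a}__vs__{c.group_b}"] = {
                "endpoint_minus": ep.endpoint_minus.tolist(),
                "endpoint_plus": ep.endpoint_plus.tolist(),
                "magnitude_sd": ep.magnitude_sd,
                "n_pcs_used": ep.n_pcs_used,
            }
        except Exception:
            logger.exception("endpoint computation failed for %s vs %s",
                             c.group_a, c.group_b)

    return ElementReport(
        element=dataset.element,
        comparisons=results,
        nj_newick=tree,
        group_counts=counts,
        gpa_iterations=aligned.iterations,
        gpa_converged=aligned.converged,
        endpoints=endpoints,
    )


def report_to_rows(report: ElementReport) -> pd.DataFrame:
    """Flatten an element report into a Table-style CSV layout."""
    rows = []
    for c in report.comparisons:
        for name in BLOCK_ORDER:
            t = c.blocks[name]
            cv_key = {"size": "size", "shape": "shape", "form": "form"}.get(name)
            cv = c.cv.get(cv_key) if cv_key else None
            rows.append({
                "element": report.element,
                "comparison": f"{c.group_a} vs {c.group_b}",
                "block": name,
                "statistic_label": t.statistic_label,
                "statistic": t.statistic_value,
                "df1": t.dfs[0] if t.dfs else np.nan,
                "df2": t.dfs[1] if t.dfs else np.nan,
                "p_value": t.p_value,
                "p_adjusted": t.p_adjusted,
                "cv_mean": cv.mean_cv if cv else np.nan,
                "cv_ci_low": cv.ci_low if cv else np.nan,
                "cv_ci_high": cv.ci_high if cv else np.nan,
                "n_pcs_shape": c.n_pcs["shape"],
                "n_pcs_form": c.n_pcs["form"],
                "n_a": t.n_per_group.get(c.group_a, np.nan),
                "n_b": t.n_per_group.get(c.group_b, np.nan),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Config-driven entry points
# ---------------------------------------------------------------------------

def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _provenance(config: dict, params: AnalysisParams) -> dict:
    return {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": params.seed,
        "correction": params.correction,
        "fst_estimator": "G_ST (haplotype frequencies, plug-in)",
        "cv_interval": "empirical 5th/95th percentiles of replicate CV values",
        "pc_rule": f">= {params.variance_threshold:.0%} cumulative variance, "
                   "capped at min group size - 1",
    }


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def params_from_config(config: dict) -> AnalysisParams:
    allowed = AnalysisParams().__dict__.keys()
    overrides = {k: v for k, v in config.get("params", {}).items() if k in allowed}
    return AnalysisParams(**overrides)


def _load_element_dataset(element_cfg: dict, element: str) -> tuple[MorphDataset, SliderScheme | None, SymmetryScheme | None]:
    from . import io as _io

    if "tps" in element_cfg:
        configs = _io.read_tps(element_cfg["tps"], element=element)
    elif "landmark_table" in element_cfg:
        configs = _io.read_landmark_table(element_cfg["landmark_table"], element=element)
    else:
        raise ValueError(f"element {element!r} config needs 'tps' or 'landmark_table'")
    meta = _io.read_metadata(element_cfg["metadata"])
    sliders = None
    if "sliders" in element_cfg:
        sliders = _io.read_slider_scheme(element_cfg["sliders"])
    elif configs and configs[0].curves:
        sliders = _io.derive_sliders(configs[0])
    symmetry = None
    if "symmetry_pairs" in element_cfg:
        symmetry = _io.read_symmetry_scheme(
            element_cfg["symmetry_pairs"], element_cfg.get("symmetry_midline", ())
        )
    return join_metadata(configs, meta), sliders, symmetry


def run_comparisons(config: dict, outdir: str | Path) -> list[ElementReport]:
    """Run the configured per-element comparison batteries and write reports.

    ``config`` maps element names to dataset paths and schemes, lists the
    comparison pairs, and may override analysis parameters.  Writes one CSV
    and one JSON report per element plus a newick tree and endpoint JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = params_from_config(config)
    reports = []
    for element, element_cfg in config["elements"].items():
        dataset, sliders, symmetry = _load_element_dataset(element_cfg, element)
        pairs = [tuple(p) for p in config.get("comparisons", [])]
        report = analyze_element(dataset, pairs, params, sliders, symmetry)
        reports.append(report)
        report_to_rows(report).to_csv(outdir / f"{element}_comparisons.csv", index=False)
        payload = report.to_dict()
        payload["provenance"] = _provenance(config, params)
        with open(outdir / f"{element}_report.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        if report.nj_newick:
            (outdir / f"{element}_nj.nwk").write_text(report.nj_newick + "\n")
        try:
            from .plotting import save_wireframes

            save_wireframes(report, outdir)
        except Exception:
            logger.exception("wireframe rendering failed for %s", element)
    return reports


def run_haplotype_contrasts(config: dict, outdir: str | Path) -> pd.DataFrame:
    """F_ST + permutation p per configured pair of groups, plus a subclade
    percentage table; both written to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = params_from_config(config)
    assignments = pd.read_csv(config["haplotypes"]["assignments"])
    known = set(assignments["group"])
    rows = []
    for pair in config["haplotypes"]["contrasts"]:
        a, b = pair
        for g in (a, b):
            if g not in known:
                raise ValueError(f"unknown group {g!r} in haplotype contrast")
        sub = assignments[assignments["group"].isin([a, b])]
        res = fst_permutation_test(
            sub, n_perm=params.n_perm,
            seed=_spawn_seed(params.seed, "fst", a, b),
        )
        rows.append({"group_a": a, "group_b": b, **res.to_dict()})
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "fst_contrasts.csv", index=False)
    freq = subclade_frequency_table(
        assignments, grouping=config["haplotypes"].get("grouping", "group")
    )
    freq.to_csv(outdir / "subclade_frequencies.csv")
    counts = build_counts(assignments)
    counts.to_frame().to_csv(outdir / "haplotype_counts.csv")
    with open(outdir / "fst_report.json", "w") as fh:
        json.dump({"contrasts": rows, "provenance": _provenance(config, params)},
                  fh, indent=2, sort_keys=True)
    return table
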