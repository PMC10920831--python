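"""Pipeline orchestration and the statistical comparisons of the report.

``run_pipeline`` executes the full chain — synthetic assay pair, behavioral
epoch detection, trace preprocessing, population geometry, decoding and
bootstrap cell classification — and assembles a machine-readable results
bundle.  Nonparametric two-tailed Wilcoxon signed-rank / rank-sum tests are
the default comparisons; one-sample t-tests are available against stated
constants, and declared p-value families are adjusted by the
Benjamini-Hochberg false-discovery-rate procedure.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import behavior as behavior_mod
from . import geometry, models, synth, traces as traces_mod
from .config import PipelineConfig
from .datatypes import BehaviorEpochs, CoRegistrationMap, StatResult

EXACT_N = 25  # exact rank distributions at or below this sample size


# ---------------------------------------------------------------------------
# statistical tests
# ---------------------------------------------------------------------------


def paired_and_unpaired_tests(
    x: np.ndarray,
    y: np.ndarray,
    paired: bool,
    name: str = "",
    family: str | None = None,
) -> StatResult:
    """Two-tailed Wilcoxon signed-rank (paired) or rank-sum (unpaired) test.

    Exact rank distributions are used for n <= 25 per group, the normal
    approximation above.  All-zero paired differences return p = 1 with a
    flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    flags: list[str] = []
    if paired:
        if x.size != y.size:
            raise ValueError("paired samples must have equal length")
        if x.size < 2:
            raise ValueError("need n >= 2")
        diff = x - y
        if np.all(diff == 0):
            return StatResult(
                name=name,
                test="wilcoxon_signed_rank",
                statistic=0.0,
                p_value=1.0,
                n=(x.size, y.size),
                family=family,
                flags=["all-zero differences"],
            )
        method = "exact" if x.size <= EXACT_N else "approx"
        try:
            res = stats.wilcoxon(x, y, method=method)
        except ValueError:  # zeros/ties force the approximation
            res = stats.wilcoxon(x, y, method="approx")
            flags.append("ties: normal approximation")
        z = None
        if method == "approx" or "zstatistic" in getattr(res, "_fields", ()):
            z = getattr(res, "zstatistic", None)
        return StatResult(
            name=name,
            test="wilcoxon_signed_rank",
            statistic=float(res.statistic),
            z_value=None if z is None else float(z),
            p_value=float(res.pvalue),
            n=(x.size, y.size),
            family=family,
            flags=flags,
        )
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 per group")
    if x.size <= EXACT_N and y.size <= EXACT_N:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return StatResult(
            name=name,
            test="wilcoxon_rank_sum",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            n=(x.size, y.size),
            family=family,
            flags=["exact"],
        )
    z, p = stats.ranksums(x, y)
    return StatResult(
        name=name,
        test="wilcoxon_rank_sum",
        statistic=float(z),
        z_value=float(z),
        p_value=float(p),
        n=(x.size, y.size),
        family=family,
    )


def one_sample_t(
    x: np.ndarray, popmean: float, name: str = "", family: str | None = None
) -> StatResult:
    """Two-tailed one-sample t-test against a stated constant."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2")
    t, p = stats.ttest_1samp(x, popmean)
    if np.isnan(p):  # zero variance exactly at popmean
        t, p = 0.0, 1.0
    return StatResult(
        name=name,
        test="one_sample_t",
        statistic=float(t),
        p_value=float(p),
        n=(x.size,),
        family=family,
    )


def fdr_adjust(p_values: np.ndarray, family: str = "") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_families(results: list[StatResult]) -> None:
    """FDR-adjust p-values within each declared family, in place."""
    by_family: dict[str, list[StatResult]] = {}
    for r in results:
        if r.family is not None and not np.isnan(r.p_value):
            by_family.setdefault(r.family, []).append(r)
    for family, group in by_family.items():
        q = fdr_adjust([r.p_value for r in group], family)
        for r, qv in zip(group, q):
            r.q_value = float(qv)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _stage(stage: str):
    """Decorator-less stage guard: returns a callable runner."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(stage, str(exc)) from exc
            return False

    return _Ctx()


def _merged_epochs(
    detected_approach: BehaviorEpochs, planted: BehaviorEpochs
) -> BehaviorEpochs:
    """Pipeline epochs: detector-derived approach plus the manually-scored
    (here: generator-supplied) eat and rear epochs."""
    entries = list(detected_approach.entries)
    entries += [e for e in planted.entries if e[0] in ("eat", "rear")]
    return BehaviorEpochs(entries)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full synthetic-session analysis and return the results bundle.

    The bundle mirrors the study's main readouts: silhouette scores against
    their permutation chance, matched-sample decoding accuracies against the
    50% chance level, cross-assay Mahalanobis/center-distance conservation
    with rank-sum comparisons, bootstrap cell-classification counts per
    behavior, and cross-assay weight/profile correlations.  Every random
    stage derives its seed from ``config.seed``, so a fixed config gives
    byte-identical machine-readable results.
    """
    config.validate()
    log: list[str] = [f"seed={config.seed}"]
    seq = np.random.SeedSequence(config.seed)
    seeds = [int(s) for s in seq.generate_state(8) >> 1]
    stat_results: list[StatResult] = []
    results: dict = {"config_seed": config.seed}

    with _stage("synth"):
        bundle_a, bundle_b, coreg = synth.generate_assay_pair(
            config.generator, overlap={"eat"}, seed=seeds[0]
        )
        log.append(
            f"synth: {config.generator.n_cells} cells, "
            f"{config.generator.duration} s, {len(coreg)} co-registered pairs"
        )

    with _stage("behavior"):
        sessions = {}
        for tag, bundle in (("A", bundle_a), ("B", bundle_b)):
            detected = behavior_mod.detect_approach(
                bundle.pose,
                min_decrease=config.min_decrease,
                min_speed=config.min_speed,
                jitter_tolerance=config.jitter_tolerance,
                speed_smoothing=config.speed_smoothing,
                head_definition=config.head_definition,
            )
            epochs = _merged_epochs(detected, bundle.epochs)
            sessions[tag] = {"bundle": bundle, "epochs": epochs}
            log.append(
                f"behavior[{tag}]: {detected.count('approach')} approach "
                f"epochs detected, {bundle.epochs.count('approach')} planted"
            )

    with _stage("traces"):
        for tag, sess in sessions.items():
            filtered, excluded = traces_mod.variance_filter(
                sess["bundle"].traces, config.variance_fraction
            )
            sess["traces"] = filtered
            log.append(f"traces[{tag}]: kept {filtered.n_cells}, dropped {len(excluded)}")
        kept_a = set(sessions["A"]["traces"].cell_ids)
        kept_b = set(sessions["B"]["traces"].cell_ids)
        coreg_pairs = [
            (a, b) for a, b in coreg.pairs if a in kept_a and b in kept_b
        ]
        coreg = CoRegistrationMap(coreg_pairs)

    with _stage("geometry"):
        results["geometry"] = {}
        for tag, sess in sessions.items():
            tr = sess["traces"]
            labels = behavior_mod.rasterize(sess["epochs"], tr.time)
            sess["labels"] = labels
            emb = geometry.embed_pca(
                tr,
                labels,
                n_components=config.n_components,
                zscore=config.zscore_before_pca,
            )
            chance = geometry.chance_silhouette(
                emb, n_shuffles=config.silhouette_shuffles, seed=seeds[1]
            )
            results["geometry"][tag] = {
                "silhouette": chance["observed"],
                "chance_mean": float(np.mean(chance["null"])),
                "percentile": chance["percentile"],
                "explained_variance": [float(v) for v in emb.explained_variance],
            }

        joint, tags = geometry.concatenate_coregistered(
            sessions["A"]["traces"], sessions["B"]["traces"], coreg
        )
        joint_labels = np.concatenate([sessions["A"]["labels"], sessions["B"]["labels"]])
        if config.distance_space == "pca":
            emb_joint = geometry.embed_pca(
                joint, joint_labels, n_components=config.n_components,
                zscore=config.zscore_before_pca,
                assay=tags,
            )
            X = emb_joint.coords
            lab = emb_joint.labels
            tag_arr = emb_joint.assay
        else:
            X = joint.values.T
            lab = joint_labels
            tag_arr = tags
        d_eat = geometry.cross_assay_distances(X, tag_arr, lab, "eat")
        d_app = geometry.cross_assay_distances(X, tag_arr, lab, "approach")
        cons = geometry.conservation_test(d_eat, d_app)
        cons.family = "conservation"
        stat_results.append(cons)

        cd = {}
        for behavior in ("eat", "approach"):
            pts = X[lab == behavior]
            cd[behavior] = geometry.center_distance(pts)
        center = paired_and_unpaired_tests(
            cd["eat"], cd["approach"], paired=False,
            name="center_distance_eat_vs_approach", family="conservation",
        )
        center.direction = (
            "eat more conserved"
            if np.median(cd["eat"]) < np.median(cd["approach"])
            else "approach more conserved"
        )
        stat_results.append(center)
        results["conservation"] = {
            "median_mahalanobis_eat": float(np.median(d_eat)),
            "median_mahalanobis_approach": float(np.median(d_app)),
            "direction": cons.direction,
            "rank_sum_z": cons.z_value,
            "rank_sum_p": cons.p_value,
        }

    with _stage("decoding"):
        results["decoding"] = {}
        for tag, sess in sessions.items():
            for behavior in ("approach", "eat"):
                key = f"{tag}:{behavior}"
                if not models.session_inclusion(
                    sess["epochs"], behavior, config.min_count
                ):
                    results["decoding"][key] = {"included": False}
                    continue
                ds = models.build_decoding_dataset(
                    sess["traces"],
                    sess["epochs"],
                    behavior,
                    window_after_onset=config.window_after_onset,
                    seed=seeds[2],
                    zscore=config.zscore_features,
                )
                res = models.crossval_decode(
                    ds, k=config.n_folds, min_gap=config.min_gap, seed=seeds[3]
                )
                results["decoding"][key] = {
                    "included": True,
                    "fold_accuracies": [round(a, 10) for a in res.fold_accuracies],
                    "mean_accuracy": round(res.mean_accuracy, 10),
                    "chance": res.chance,
                }
                t = one_sample_t(
                    res.fold_accuracies, 0.5,
                    name=f"decoding_{key}_vs_chance", family="decoding",
                )
                stat_results.append(t)

    with _stage("classification"):
        results["cell_classes"] = {}
        for tag, sess in sessions.items():
            for behavior in ("eat", "approach"):
                classes = models.classify_cells(
                    sess["traces"],
                    sess["epochs"],
                    behavior,
                    n_shuffles=config.n_shuffles,
                    quantile=config.quantile,
                    seed=seeds[4],
                )
                counts = {"+": 0, "-": 0, "ns": 0}
                for c in classes:
                    counts[c.label] += 1
                results["cell_classes"][f"{tag}:{behavior}"] = counts
                sess[f"classes_{behavior}"] = {c.cell_id: c for c in classes}

    with _stage("correlations"):
        results["correlations"] = {}
        for behavior in ("eat", "approach"):
            wa = {
                cid: c.glm_weight
                for cid, c in sessions["A"][f"classes_{behavior}"].items()
            }
            wb = {
                cid: c.glm_weight
                for cid, c in sessions["B"][f"classes_{behavior}"].items()
            }
            wc = models.weight_correlation(wa, wb, coreg)
            results["correlations"][f"weights_{behavior}"] = wc
            if wc["flag"] is None:
                stat_results.append(
                    StatResult(
                        name=f"weight_correlation_{behavior}",
                        test="spearman",
                        statistic=wc["rho"],
                        p_value=wc["p_value"],
                        n=(wc["n"],),
                        family="correlations",
                    )
                )
        profs = {}
        for behavior in ("eat", "approach"):
            tensors = {}
            for tag, sess in sessions.items():
                onsets = sess["epochs"].onsets(behavior)
                tensors[tag] = traces_mod.align_to_events(
                    sess["traces"], onsets,
                    (config.pre_window, config.post_window), label=behavior,
                )
            shared = [a for a, b in coreg.pairs]
            profs[behavior] = models.profile_correlation(
                tensors["A"], tensors["B"], cells=shared
            )
            results["correlations"][f"profiles_{behavior}"] = profs[behavior]
        z, p = models.fisher_r_to_z(
            profs["eat"]["rho"], profs["approach"]["rho"],
            profs["eat"]["n"], profs["approach"]["n"],
        )
        results["correlations"]["profile_fisher"] = {"z": z, "p_value": p}

    adjust_families(stat_results)
    results["stats"] = [r.to_dict() for r in stat_results]
    results["log"] = log

    if out_dir is not None:
        write_report(results, sessions, out_dir)
    return results


def write_report(results: dict, sessions: dict, out_dir: str | Path) -> None:
    """Write the machine-readable results, class tables, summary figure and
    run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = results.get("log", [])
    payload = {k: v for k, v in results.items() if k != "log"}
    with open(out / "results.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    rows = []
    for tag, sess in sessions.items():
        for behavior in ("eat", "approach"):
            for cid, c in sess.get(f"classes_{behavior}", {}).items():
                rows.append(
                    {
                        "session": tag,
                        "behavior": behavior,
                        "cell_id": cid,
                        "glm_weight": c.glm_weight,
                        "null_quantile": c.null_quantile,
                        "class": c.label,
                    }
                )
    if rows:
        pd.DataFrame(rows).to_csv(out / "cell_classes.csv", index=False)
    _summary_figure(results, out / "summary.png")
    import feedscope

    with open(out / "run.log", "w") as fh:
        fh.write(f"feedscope {feedscope.__version__}\n")
        fh.write("\n".join(log) + "\n")


def _summary_figure(results: dict, path: Path) -> None:
    """Four-panel overview: silhouette vs chance, decoding vs 50%,
    cross-assay conservation, and cell-class counts."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 7))

    ax = axes[0, 0]
    tags = sorted(results["geometry"])
    ax.bar(tags, [results["geometry"][t]["silhouette"] for t in tags], color="tab:blue")
    ax.axhline(0.0, color="red", ls=":", label="chance")
    ax.set_ylabel("mean silhouette")
    ax.set_title("Behavior clustering")
    ax.legend(frameon=False)

    ax = axes[0, 1]
    keys = [k for k, v in results["decoding"].items() if v.get("included")]
    ax.bar(keys, [results["decoding"][k]["mean_accuracy"] for k in keys],
           color="tab:green")
    ax.axhline(0.5, color="red", ls=":", label="chance 50%")
    ax.set_ylim(0, 1)
    ax.set_ylabel("decoding accuracy")
    ax.set_title("Matched-sample decoding")
    ax.tick_params(axis="x", rotation=45)
    ax.legend(frameon=False)

    ax = axes[1, 0]
    cons = results["conservation"]
    ax.bar(["eat", "approach"],
           [cons["median_mahalanobis_eat"], cons["median_mahalanobis_approach"]],
           color=["tab:blue", "tab:orange"])
    ax.set_ylabel("median cross-assay $d_M$")
    ax.set_title(f"Conservation ({cons['direction']})")

    ax = axes[1, 1]
    classes = results["cell_classes"]
    keys = sorted(classes)
    bottom = np.zeros(len(keys))
    for label, color in (("+", "tab:red"), ("-", "tab:blue"), ("ns", "0.8")):
        vals = np.array([classes[k][label] for k in keys], dtype=float)
        ax.bar(keys, vals, bottom=bottom, label=label, color=color)
        bottom += vals
    ax.set_ylabel("cells")
    ax.set_title("Bootstrap GLM classes")
    ax.tick_params(axis="x", rotation=45)
    ax.legend(frameon=False)

    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
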