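"""Mating-type coding, Bayes-factor monophyly statistics, transition
counting, and the end-to-end study workflow.

The trait coding follows the 'any-instance' rule: a species fixed for the
ancestral (outcrossing) condition scores 0, a species in which the derived
(selfing) condition occurs in any sampled individual — polymorphic or fixed —
scores 1, and species of unknown mating type are coded missing.

Bayes-factor monophyly testing consumes externally estimated marginal tree
log-likelihoods of an unconstrained analysis and one in which the selfing
species are constrained to be monophyletic; the package only computes the
statistic and assigns the conventional evidence band (≤2 none, 2–6 positive,
6–10 strong, >10 very strong).
"""

from __future__ import annotations

import hashlib
import json
import platform
import time
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .asr import AncestralStates
from .errors import DataError, SelfswitchError
from .params import BisseParams
from .treeio import Tree, bipartition_index, branching_times, ltt_curve

MATING_CATEGORIES = ("Outcrossing", "Dimorphic", "Trimorphic", "Unknown")


# --------------------------------------------------------------------- #
# trait coding
# --------------------------------------------------------------------- #

def load_mating_type_table(source: Union[str, Path, pd.DataFrame]) -> Dict[str, str]:
    """Read a species → mating-type table from TSV (columns ``species`` and
    ``mating_type``) or an equivalent DataFrame."""
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep="\t")
    if "species" not in df or "mating_type" not in df:
        raise DataError("table needs 'species' and 'mating_type' columns")
    species = df["species"].astype(str)
    if species.duplicated().any():
        raise DataError(f"duplicate species: "
                        f"{sorted(species[species.duplicated()])}")
    if len(df) == 0:
        raise DataError("empty mating-type table")
    return dict(zip(species, df["mating_type"].astype(str)))


def clade_c_mating_types() -> Dict[str, str]:
    """The packaged 30-species mating-type table of the study clade."""
    with resources.files("selfswitch.data").joinpath(
            "clade_c_mating_types.tsv").open() as fh:
        return load_mating_type_table(pd.read_csv(fh, sep="\t"))


def code_any_instance(table: Dict[str, str]) -> Dict[str, Optional[int]]:
    """'Any-instance' binary coding of mating types.

    Outcrossing → 0; Dimorphic or Trimorphic (selfing occurs in at least some
    individuals) → 1; Unknown → missing (None).
    """
    bad = sorted(sp for sp, c in table.items() if c not in MATING_CATEGORIES)
    if bad:
        raise DataError(f"unrecognized mating-type categories for: {bad}")
    out: Dict[str, Optional[int]] = {}
    for sp, c in table.items():
        out[sp] = None if c == "Unknown" else int(c in ("Dimorphic", "Trimorphic"))
    return out


def load_tip_states(source: Union[str, Path, pd.DataFrame]) -> Dict[str, Optional[int]]:
    """Read a binary tip-state TSV: columns ``species`` and either ``state``
    (0/1/NA) or ``mating_type`` (then any-instance coding is applied)."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    if "state" in df:
        out: Dict[str, Optional[int]] = {}
        for sp, v in zip(df["species"].astype(str), df["state"]):
            out[sp] = None if pd.isna(v) else int(v)
        return out
    return code_any_instance(load_mating_type_table(df))


def write_tip_states(tips: Dict[str, Optional[int]], path: Union[str, Path]) -> None:
    rows = [{"species": k, "state": ("NA" if v is None else v)}
            for k, v in sorted(tips.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------- #
# Bayes factors
# --------------------------------------------------------------------- #

EVIDENCE_BANDS = ((2.0, "none"), (6.0, "positive"), (10.0, "strong"),
                  (np.inf, "very strong"))


@dataclass(frozen=True)
class BFResult:
    """Bayes-factor comparison of unconstrained vs monophyly-constrained runs."""

    lnl_unconstrained: float
    lnl_constrained: float
    statistic: float
    band: str


def evidence_band(statistic: float) -> str:
    for upper, band in EVIDENCE_BANDS:
        if statistic <= upper:
            return band
    return "very strong"


def bf_statistic(lnl_unconstrained: float, lnl_constrained: float,
                 doubled: bool = False) -> BFResult:
    """Evidence against the constrained (null) model.

    The statistic is the difference of marginal log tree likelihoods,
    unconstrained − constrained (the arithmetic that reproduces the study's
    printed values); ``doubled=True`` gives the textbook 2·Δln form instead.
    A negative statistic (constraint fits better) is reported with band
    "none" and a warning.
    """
    if not (np.isfinite(lnl_unconstrained) and np.isfinite(lnl_constrained)):
        raise DataError("marginal log-likelihoods must be finite")
    stat = lnl_unconstrained - lnl_constrained
    if doubled:
        stat *= 2.0
    if stat < 0:
        warnings.warn("constrained model has the higher marginal likelihood; "
                      "no evidence against monophyly", stacklevel=2)
        return BFResult(lnl_unconstrained, lnl_constrained, stat, "none")
    return BFResult(lnl_unconstrained, lnl_constrained, stat,
                    evidence_band(stat))


def monophyly_tests() -> pd.DataFrame:
    """The packaged monophyly-test inputs (marginal log tree likelihoods of
    the unconstrained analysis and three selfer-monophyly constraints), with
    the BF statistic and band recomputed from them."""
    with resources.files("selfswitch.data").joinpath(
            "monophyly_marginal_likelihoods.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    ref = float(df.loc[df.constraint == "none", "marginal_lnl"].iloc[0])
    stats, bands = [], []
    for _, row in df.iterrows():
        if row.constraint == "none":
            stats.append(np.nan)
            bands.append("")
        else:
            r = bf_statistic(ref, float(row.marginal_lnl))
            stats.append(r.statistic)
            bands.append(r.band)
    df["bf"] = stats
    df["band"] = bands
    return df


# --------------------------------------------------------------------- #
# transition counting
# --------------------------------------------------------------------- #

@dataclass
class TransitionCount:
    n_gain: int          # 0 → 1 (outcrossing → selfing)
    n_loss: int          # 1 → 0 (reversals)
    n_tied_nodes: int    # nodes at exactly P = 0.5, resolved to state 0


def count_transitions(anc: AncestralStates, tips: Dict[str, Optional[int]],
                      tree: Tree, missing: str = "impute") -> TransitionCount:
    """Count state changes along edges given modal node states.

    Each internal node takes its modal ASR state (P(1) > 0.5 → 1; exact ties
    resolve to the ancestral state 0 and are flagged); tips take their
    observed state.  Missing tips either inherit their parent's modal state
    (``missing="impute"``, so their pendant edge cannot contribute) or have
    their pendant edges excluded (``missing="strict"``).
    """
    if missing not in ("impute", "strict"):
        raise DataError("missing must be 'impute' or 'strict'")
    dt = tree.dendropy_tree
    clade: Dict[int, frozenset] = {}
    modal: Dict[int, Optional[int]] = {}
    ties = 0
    for node in dt.postorder_node_iter():
        kids = node.child_nodes()
        if not kids:
            name = str(node.taxon.label)
            clade[id(node)] = frozenset([name])
            modal[id(node)] = tips.get(name)
        else:
            s: frozenset = frozenset()
            for k in kids:
                s |= clade[id(k)]
            clade[id(node)] = s
            if s not in anc.probs:
                raise DataError(f"no ancestral probabilities for node {set(s)}")
            p1 = float(anc.probs[s][1])
            if p1 == 0.5:
                ties += 1
            modal[id(node)] = int(p1 > 0.5)
    gains = losses = 0
    for node in dt.preorder_node_iter():
        if node is dt.seed_node:
            continue
        child = modal[id(node)]
        parent = modal[id(node.parent_node)]
        if child is None:                      # missing tip
            if missing == "impute":
                modal[id(node)] = parent
            continue
        if parent != child:
            if child == 1:
                gains += 1
            else:
                losses += 1
    return TransitionCount(n_gain=gains, n_loss=losses, n_tied_nodes=ties)


# --------------------------------------------------------------------- #
# end-to-end workflow
# --------------------------------------------------------------------- #

@dataclass
class StudyConfig:
    """Configuration of the end-to-end analysis.

    Either point ``tree_file``/``states_file`` at data on disk (newick lines
    or NEXUS; TSV) or leave them None to run on the built-in clade-C-like
    synthetic dataset.  All randomness flows from ``seed``.
    """

    tree_file: Optional[str] = None
    states_file: Optional[str] = None
    seed: int = 0
    n_synthetic_trees: int = 100
    daicrc_reps: int = 200
    bisse_trees: int = 16          # trees used for the BiSSE model suite
    mk2_generations: int = 20_000
    mk2_burnin: int = 2_000
    mk2_trees: int = 50
    bf_table: Optional[str] = None  # TSV like the packaged monophyly table

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "StudyConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class StudyReport:
    """All artifacts of one :func:`run_study` run."""

    diversification: pd.DataFrame
    daicrc: Optional[dict]
    bisse_table: pd.DataFrame
    mk2_posterior_summary: dict
    mk2_asr: pd.DataFrame
    bisse_asr: pd.DataFrame
    transitions: TransitionCount
    ltt: pd.DataFrame
    bayes_factors: pd.DataFrame
    manifest: dict

    def write(self, outdir: Union[str, Path]) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.diversification.to_csv(out / "diversification.tsv", sep="\t",
                                    index=False, float_format="%.6g")
        self.bisse_table.to_csv(out / "bisse_models.tsv", sep="\t",
                                index=False, float_format="%.6g")
        self.mk2_asr.to_csv(out / "mk2_asr.tsv", sep="\t", index=False,
                            float_format="%.6g")
        self.bisse_asr.to_csv(out / "bisse_asr.tsv", sep="\t", index=False,
                              float_format="%.6g")
        self.ltt.to_csv(out / "ltt.tsv", sep="\t", index=False,
                        float_format="%.6g")
        self.bayes_factors.to_csv(out / "bayes_factors.tsv", sep="\t",
                                  index=False, float_format="%.6g")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def _asr_frame(anc: AncestralStates) -> pd.DataFrame:
    rows = []
    for bp, p in sorted(anc.probs.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0]))):
        rows.append({"bipartition": "|".join(sorted(bp)),
                     "p0": float(p[0]), "p1": float(p[1]),
                     "support": anc.support.get(bp, 1)})
    return pd.DataFrame(rows)


def _stage(name: str, fn, manifest: dict):
    t0 = time.time()
    try:
        out = fn()
    except Exception as exc:
        raise SelfswitchError(f"stage {name!r} failed: {exc}") from exc
    manifest["stages"][name] = {"wall_s": round(time.time() - t0, 3)}
    return out


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full workflow: diversification-model table, rate-constancy
    test, BiSSE model suite, Mk2 MCMC, Mk2 and BiSSE ancestral states,
    transition counts, LTT data and Bayes-factor table.

    Deterministic: identical config (including seed) gives identical outputs.
    """
    from . import __version__, bisse, markov2, simulators
    from . import diversification as dv

    manifest: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
    }
    rng = np.random.default_rng(config.seed)

    # --- data -----------------------------------------------------------
    def load():
        if config.tree_file is None:
            ds = simulators.make_clade_c_like_dataset(
                rng=rng, n_trees=config.n_synthetic_trees)
            manifest["data"] = {"source": "synthetic clade-C-like dataset",
                                "n_trees": len(ds.trees)}
            return ds.trees, ds.tip_states, ds.base_tree
        text = Path(config.tree_file).read_text()
        from .treeio import parse_newick_lines, parse_nexus_trees
        if text.lstrip().startswith("#NEXUS"):
            trees = parse_nexus_trees(text)
        else:
            trees = parse_newick_lines(text)
        tips = load_tip_states(config.states_file)
        manifest["data"] = {
            "source": config.tree_file,
            "n_trees": len(trees),
            "tree_digest": hashlib.sha256(text.encode()).hexdigest()[:16],
        }
        return trees, tips, trees[0]
    trees, tips, ref_tree = _stage("load", load, manifest)

    # --- diversification -------------------------------------------------
    bt = branching_times(ref_tree)
    div_table = _stage("fit_div",
                       lambda: dv.fits_to_frame(dv.fit_all(bt)), manifest)

    if config.daicrc_reps > 0:
        res = _stage("daicrc", lambda: dv.daicrc_test(
            bt, reps=config.daicrc_reps,
            seed=int(rng.integers(2 ** 31))), manifest)
        daicrc = {"observed": res.observed, "p_value": res.p_value,
                  "reps": config.daicrc_reps,
                  "critical_95": res.critical_value()}
    else:
        daicrc = None
        manifest["stages"]["daicrc"] = "skipped (reps=0)"

    # --- BiSSE suite ------------------------------------------------------
    suite_trees = trees[:config.bisse_trees]
    suite = _stage("fit_bisse", lambda: bisse.bisse_model_suite(
        suite_trees, tips), manifest)
    best_name = suite.table.model.iloc[0]
    best_med = suite.fits[best_name].medians
    best_params = BisseParams(*[best_med[k] for k in
                                ("lam_o", "lam_s", "mu_o", "mu_s",
                                 "q_os", "q_so")])

    # --- Mk2 --------------------------------------------------------------
    def run_mk2():
        settings = markov2.Mk2McmcSettings(
            generations=config.mk2_generations, burnin=config.mk2_burnin,
            seed=int(rng.integers(2 ** 31)))
        post = markov2.mk2_mcmc(trees[:config.mk2_trees], tips, settings)
        return post
    post = _stage("mk2_mcmc", run_mk2, manifest)
    mk2_summary = post.summary()
    mk2_summary["acceptance_rate"] = post.acceptance_rate

    def mk2_asr():
        pb = post.post_burnin()
        med = markov2.Mk2Params(float(np.median(pb.q01)),
                                float(np.median(pb.q10)))
        per_tree = [markov2.mk2_asr_marginal(t, tips, med)
                    for t in trees[:config.mk2_trees]]
        from .asr import asr_average
        return asr_average(per_tree, ref_tree)
    mk2_anc = _stage("mk2_asr", mk2_asr, manifest)

    # --- BiSSE ASR + transitions -----------------------------------------
    def b_asr():
        from .asr import asr_average
        per_tree = [bisse.bisse_asr_marginal(t, tips, best_params)
                    for t in suite_trees]
        return asr_average(per_tree, ref_tree)
    bisse_anc = _stage("bisse_asr", b_asr, manifest)
    trans = count_transitions(bisse_anc, tips, ref_tree)

    # --- LTT + BF ---------------------------------------------------------
    c = ltt_curve(ref_tree)
    ltt_df = pd.DataFrame({"age": c.ages, "lineages": c.counts})
    if config.bf_table is not None:
        bf_raw = pd.read_csv(config.bf_table, sep="\t")
        ref = float(bf_raw.loc[bf_raw.constraint == "none",
                               "marginal_lnl"].iloc[0])
        rows = []
        for _, row in bf_raw.iterrows():
            if row.constraint == "none":
                continue
            r = bf_statistic(ref, float(row.marginal_lnl))
            rows.append({"constraint": row.constraint, "bf": r.statistic,
                         "band": r.band})
        bf_df = pd.DataFrame(rows)
    else:
        bf_df = monophyly_tests()

    manifest["best_bisse_model"] = best_name
    manifest["transitions"] = {"gains": trans.n_gain, "losses": trans.n_loss}
    return StudyReport(
        diversification=div_table, daicrc=daicrc, bisse_table=suite.table,
        mk2_posterior_summary=mk2_summary, mk2_asr=_asr_frame(mk2_anc),
        bisse_asr=_asr_frame(bisse_anc), transitions=trans, ltt=ltt_df,
        bayes_factors=bf_df, manifest=manifest)
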