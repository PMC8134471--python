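"""Synthetic connectome datasets with planted brain-behavior structure.

The generator emulates the structure of a task-fMRI irritability study:
~69 youths, a 268-node parcellation (smaller atlases for test speed), one
symmetric Fisher-z connectivity matrix per subject per task condition
(frustration / nonfrustration), a right-skewed bounded irritability score
(ARI: integers 0-12, population mean 1.79 and SD 2.04), demographic and
motion covariates, and a sparse set of edges whose connectivity is linearly
coupled to the behavior — present only in the frustration condition when
``condition_specific`` is set, mirroring the state-dependence the analysis is
meant to detect.

Matrices are generated directly on the Fisher-z scale (edge = baseline +
signal + Gaussian noise) rather than via simulated time series: CPM operates
on z-edges, and direct generation gives exact control of the planted
edge-behavior correlation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import (Atlas, CANONICAL_NETWORKS, CONDITIONS, ConnectivityMatrix,
                    PhenotypeTable, devectorize, n_edges)

#: Gamma parameters whose rounded-and-clipped discretization on 0..12
#: reproduces the target score moments (mean 1.79, SD 2.04) exactly.
ARI_GAMMA_SHAPE = 0.8019747152016875
ARI_GAMMA_SCALE = 2.275403571184091

#: Parent-report analogue (target mean 2.80, SD 3.35), same construction.
PARENT_GAMMA_SHAPE = 0.698
PARENT_GAMMA_SCALE = 4.007

_REGIONS = ("prefrontal", "motor", "insula", "parietal", "temporal",
            "occipital", "limbic", "cerebellum", "subcortex", "brainstem")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generating parameters of one synthetic dataset.

    ``effect_r`` is the population correlation between each planted signal
    edge and the standardized behavior score; ``confound_strength`` couples
    the confound edge set to standardized motion the same way (as a
    correlation magnitude).  ``behavior_motion_r`` correlates the behavior
    itself with motion through a Gaussian copula, so a nonzero value plus
    confound edges yields a dataset whose brain-behavior association is
    carried entirely by motion.
    """

    n_subjects: int = 69
    n_nodes: int = 60
    n_signal_pos: int = 40
    n_signal_neg: int = 0
    n_confound_edges: int = 0
    effect_r: float = 0.4
    confound_strength: float = 0.0
    behavior_motion_r: float = 0.0
    edge_noise_sd: float = 0.2
    baseline_mean: float = 0.3
    baseline_sd: float = 0.15
    ari_shape: float = ARI_GAMMA_SHAPE
    ari_scale: float = ARI_GAMMA_SCALE
    condition_specific: bool = True
    n_missing_parent: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        e = n_edges(self.n_nodes)
        if self.n_signal_pos + self.n_signal_neg + self.n_confound_edges > e:
            raise ValueError(
                f"planted edge sets exceed the {e} available edges")
        if not 0.0 <= self.effect_r < 1.0:
            raise ValueError("effect_r must be in [0, 1)")
        if not 0.0 <= self.confound_strength < 1.0:
            raise ValueError("confound_strength must be in [0, 1)")
        if not -1.0 < self.behavior_motion_r < 1.0:
            raise ValueError("behavior_motion_r must be in (-1, 1)")
        if self.edge_noise_sd < 0:
            raise ValueError("edge_noise_sd must be >= 0")
        if min(self.n_subjects, self.n_nodes, self.n_signal_pos,
               self.n_signal_neg, self.n_confound_edges) < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class SyntheticDataset:
    """Generated atlas, per-condition edge data, phenotypes, and ground truth."""

    atlas: Atlas
    edges: dict[str, np.ndarray]  # condition -> n_subjects x E Fisher-z edges
    phenotypes: PhenotypeTable
    ground_truth: dict
    spec: SyntheticSpec

    @property
    def subject_ids(self) -> list[str]:
        return self.phenotypes.subject_ids

    def edge_matrix(self, condition: str) -> np.ndarray:
        if condition == "difference":
            return self.edges["frustration"] - self.edges["nonfrustration"]
        return self.edges[condition]

    def matrices(self, condition: str) -> list[ConnectivityMatrix]:
        """Materialize per-subject symmetric matrices for one condition."""
        k = self.atlas.n_nodes
        return [ConnectivityMatrix(sid, condition, devectorize(row, k))
                for sid, row in zip(self.subject_ids, self.edges[condition])]


def generate_atlas(n_nodes: int, seed: int = 0) -> Atlas:
    """Synthetic parcellation: hemispheres alternating L/R, networks assigned
    round-robin over the 10 canonical labels, centroids drawn uniformly in
    hemisphere-consistent boxes (left: x < 0, right: x > 0).
    """
    if n_nodes < len(CANONICAL_NETWORKS):
        raise ValueError(
            f"need at least {len(CANONICAL_NETWORKS)} nodes, got {n_nodes}")
    rng = np.random.default_rng(seed)
    idx = np.arange(n_nodes)
    hemi = np.where(idx % 2 == 0, "L", "R")
    net = np.array(CANONICAL_NETWORKS)[idx % len(CANONICAL_NETWORKS)]
    region = np.array(_REGIONS)[(idx // len(CANONICAL_NETWORKS)) % len(_REGIONS)]
    x = rng.uniform(5.0, 70.0, n_nodes) * np.where(hemi == "L", -1.0, 1.0)
    y = rng.uniform(-100.0, 70.0, n_nodes)
    z = rng.uniform(-50.0, 80.0, n_nodes)
    return Atlas(pd.DataFrame({
        "node_id": idx + 1, "hemisphere": hemi, "network": net,
        "region": region, "x": np.round(x, 2), "y": np.round(y, 2),
        "z": np.round(z, 2),
    }))


def _copula_scores(rng: np.random.Generator, n: int, shape: float,
                   scale: float, latent_anchor: np.ndarray | None,
                   r: float) -> np.ndarray:
    """Rounded, clipped gamma scores, optionally rank-coupled to an anchor.

    A standard-normal latent with correlation ``r`` to the (standardized)
    anchor is pushed through the gamma quantile function, preserving the
    marginal score distribution while inducing the requested association.
    """
    eps = rng.standard_normal(n)
    if latent_anchor is not None and r != 0.0:
        za = (latent_anchor - latent_anchor.mean()) / latent_anchor.std()
        latent = r * za + np.sqrt(1.0 - r * r) * eps
    else:
        latent = eps
    u = stats.norm.cdf(latent)
    raw = stats.gamma.ppf(u, a=shape, scale=scale)
    return np.clip(np.rint(raw), 0, 12).astype(int)


def generate_behavior(spec: SyntheticSpec,
                      rng: np.random.Generator | None = None,
                      motion: np.ndarray | None = None,
                      ) -> tuple[np.ndarray, pd.DataFrame]:
    """Behavior scores and covariates for ``spec.n_subjects`` subjects.

    Returns the integer child scores and a covariate frame with age (uniform
    8-22 y), sex (0 male / 1 female, 45% female), motion (lognormal, mean
    ~0.07 mm), ADHD/anxiety symptom scores, medication flags, parent scores
    (with ``n_missing_parent`` set missing), and a 1-9 state-frustration
    rating.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = spec.n_subjects
    age = rng.uniform(8.0, 22.0, n)
    sex = (rng.random(n) < 0.45).astype(int)
    # lognormal with mean 0.07 mm and SD 0.03 mm
    sigma = np.sqrt(np.log(1.0 + (0.03 / 0.07) ** 2))
    mu = np.log(0.07) - sigma**2 / 2.0
    motion = np.exp(mu + sigma * rng.standard_normal(n)) if motion is None else motion

    child = _copula_scores(rng, n, spec.ari_shape, spec.ari_scale,
                           np.log(motion), spec.behavior_motion_r)
    if np.ptp(child) == 0:
        # degenerate draw (tiny n): force minimal variance so analyses remain defined
        child = child.copy()
        child[rng.integers(0, n)] += 1
    z_child = (child - child.mean()) / child.std()
    parent = _copula_scores(rng, n, PARENT_GAMMA_SHAPE, PARENT_GAMMA_SCALE,
                            z_child, 0.55).astype(float)
    if spec.n_missing_parent:
        parent[rng.choice(n, size=min(spec.n_missing_parent, n),
                          replace=False)] = np.nan
    adhd = np.clip(np.rint(3.0 * z_child + 10.0
                           + 4.0 * rng.standard_normal(n)), 0, 54)
    anxiety = np.clip(np.rint(2.0 * z_child + 8.0
                              + 5.0 * rng.standard_normal(n)), 0, 50)
    covs = pd.DataFrame({
        "age": np.round(age, 2),
        "sex": sex,
        "motion": np.round(motion, 4),
        "adhd": adhd.astype(int),
        "anxiety": anxiety.astype(int),
        "med_stimulant": (rng.random(n) < 0.20).astype(int),
        "med_nonstimulant": (rng.random(n) < 0.10).astype(int),
        "med_antidepressant": (rng.random(n) < 0.15).astype(int),
        "med_antipsychotic": (rng.random(n) < 0.10).astype(int),
        "parent_ari": parent,
        "state_frustration": np.clip(
            np.rint(4.5 + 0.8 * z_child + 1.8 * rng.standard_normal(n)), 1, 9
        ).astype(int),
    })
    return child, covs


def _signal_beta(effect_r: float, noise_sd: float) -> float:
    """Coefficient on the standardized behavior giving the target edge-behavior
    correlation r = beta / sqrt(beta^2 + noise_sd^2).  In the noiseless limit
    any positive coefficient yields |r| = 1; unit slope is used.
    """
    if effect_r == 0.0:
        return 0.0
    if noise_sd == 0.0:
        return 1.0
    return noise_sd * effect_r / np.sqrt(1.0 - effect_r**2)


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Full synthetic dataset: atlas, phenotypes, and per-condition edges.

    Non-signal edges are Normal(baseline_e, edge_noise_sd) around per-edge
    baselines drawn once.  Planted positive (negative) edges add
    +beta (-beta) times the standardized behavior; confound edges add the
    analogous multiple of standardized log-motion.  With
    ``condition_specific`` (the default) all planted terms appear only in the
    frustration matrices; nonfrustration matrices share the baselines but are
    otherwise pure noise.  Everything is a deterministic function of
    ``spec.seed``.
    """
    root = np.random.SeedSequence(spec.seed)
    ss_atlas, ss_beh, ss_edges = root.spawn(3)
    atlas = generate_atlas(spec.n_nodes, seed=ss_atlas)
    rng = np.random.default_rng(ss_beh)
    child, covs = generate_behavior(spec, rng)

    n, e = spec.n_subjects, n_edges(spec.n_nodes)
    erng = np.random.default_rng(ss_edges)
    order = erng.permutation(e)
    pos_idx = np.sort(order[:spec.n_signal_pos])
    neg_idx = np.sort(order[spec.n_signal_pos:
                            spec.n_signal_pos + spec.n_signal_neg])
    conf_idx = np.sort(order[spec.n_signal_pos + spec.n_signal_neg:
                             spec.n_signal_pos + spec.n_signal_neg
                             + spec.n_confound_edges])
    baselines = spec.baseline_mean + spec.baseline_sd * erng.standard_normal(e)

    z_beh = (child - child.mean()) / child.std()
    motion = covs["motion"].to_numpy()
    log_m = np.log(motion)
    z_mot = (log_m - log_m.mean()) / log_m.std()
    beta = _signal_beta(spec.effect_r, spec.edge_noise_sd)
    gamma = _signal_beta(spec.confound_strength, spec.edge_noise_sd)

    signal = np.zeros((n, e))
    signal[:, pos_idx] += beta * z_beh[:, None]
    signal[:, neg_idx] -= beta * z_beh[:, None]
    signal[:, conf_idx] += gamma * z_mot[:, None]

    edges = {}
    for cond in CONDITIONS:
        noise = spec.edge_noise_sd * erng.standard_normal((n, e))
        vals = baselines[None, :] + noise
        if cond == "frustration" or not spec.condition_specific:
            vals = vals + signal
        edges[cond] = vals

    subject_ids = [f"S{i + 1:03d}" for i in range(n)]
    pheno = pd.DataFrame({"subject_id": subject_ids, "child_ari": child})
    pheno = pd.concat([pheno, covs], axis=1)
    ground_truth = {
        "pos_edges": pos_idx.tolist(),
        "neg_edges": neg_idx.tolist(),
        "confound_edges": conf_idx.tolist(),
        "beta": float(beta),
        "confound_beta": float(gamma),
        "spec": asdict(spec),
    }
    return SyntheticDataset(atlas, edges, PhenotypeTable(pheno),
                            ground_truth, spec)


def save_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write a dataset in the standard file layouts.

    Produces atlas.tsv, phenotypes.csv, one matrix text file per
    subject x condition under matrices/, a manifest.tsv, and
    ground_truth.json.  Returns the manifest path.
    """
    from .atlas import save_atlas, save_matrix, save_phenotypes

    out = Path(out_dir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    save_atlas(dataset.atlas, out / "atlas.tsv")
    save_phenotypes(dataset.phenotypes, out / "phenotypes.csv")
    rows = []
    for cond in CONDITIONS:
        for m in dataset.matrices(cond):
            rel = Path("matrices") / f"{m.subject_id}_{cond}.txt"
            save_matrix(m, out / rel)
            rows.append({"subject_id": m.subject_id, "condition": cond,
                         "path": str(rel)})
    manifest = out / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    (out / "ground_truth.json").write_text(
        json.dumps(dataset.ground_truth, indent=2))
    return manifest
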