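"""Seeded generators for state-structured single-cell atlases and signature libraries.

The atlas generator emulates a multi-subject tumor atlas with discrete
transcriptional states: each state owns a module of marker-like genes that
are near-silent elsewhere (low baseline relative expression) and strongly
elevated in that state's cells.  Counts follow a Gamma-Poisson (negative
binomial) model with log-normal library sizes, per-subject gene offsets, and
per-cell-per-gene biological log-noise.  Normal (non-neoplastic) cells carry
no module elevation and serve as the reference population.

The signature-library generator derives, for each state, a "targeting"
directional signature whose up-genes are that state's module (rank-graded
scores, optionally diluted with off-target noise genes) and its negated
"reversal" signature; random background-gene signatures provide null
candidates.  All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_preprocess import GeneExpressionMatrix
from .signatures import DirectionalSignature

__all__ = [
    "AtlasSpec",
    "GroundTruth",
    "generate_atlas",
    "generate_signature_library",
    "generate_random_signatures",
    "generate_de_table",
]

# fixed generator constants (see docs/methods.md): biological log-noise scale,
# module baseline offset, and elevation per unit of module_effect, all on the
# natural-log scale of relative expression
_BIO_NOISE_SCALE = 0.5
_MODULE_BASELINE = -2.0
_ELEVATION_SCALE = 2.0
_SUBJECT_SD = 0.15
_LIBRARY_SIGMA = 0.3
_N_MITO = 5


@dataclass
class AtlasSpec:
    """Parameters of the synthetic tumor atlas.

    ``module_effect`` is the per-unit elevation of a state's module genes in
    that state's cells (0 = null atlas); ``noise_sd`` scales the biological
    log-noise.  ``n_cells_per_state`` counts cells per state *per subject*.
    """

    n_states: int = 4
    genes_per_module: int = 50
    n_background_genes: int = 400
    n_cells_per_state: int = 200
    n_subjects: int = 4
    n_normal_cells: int = 400
    module_effect: float = 1.5
    noise_sd: float = 1.0
    dispersion: float = 0.5
    mean_library_size: float = 1200.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        for name in (
            "n_states",
            "genes_per_module",
            "n_background_genes",
            "n_cells_per_state",
            "n_subjects",
            "n_normal_cells",
        ):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be >= 1 (got {getattr(self, name)})")
        if self.noise_sd <= 0:
            problems.append(f"noise_sd must be > 0 (got {self.noise_sd})")
        if self.dispersion < 0:
            problems.append(f"dispersion must be >= 0 (got {self.dispersion})")
        if self.mean_library_size <= 0:
            problems.append(f"mean_library_size must be > 0 (got {self.mean_library_size})")
        if self.n_states > 26:
            problems.append("n_states is limited to 26 (single-letter state names)")
        if problems:
            raise ValueError("invalid atlas spec: " + "; ".join(problems))

    @property
    def state_names(self) -> list:
        return list(string.ascii_uppercase[: self.n_states])


@dataclass
class GroundTruth:
    """True cell states, module gene lists, and signature annotations."""

    states: pd.Series  # cell -> true state ("normal" for reference cells)
    modules: dict  # state -> module gene list
    background_genes: list
    module_strength: dict = field(default_factory=dict)  # state -> Series of log-means
    signatures: dict = field(default_factory=dict)  # name -> {state, direction}


def generate_atlas(spec: AtlasSpec) -> tuple:
    """Simulate a counts atlas; returns (expression, metadata, ground truth).

    Deterministic for a fixed spec (seed included): running twice yields
    byte-identical matrices.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    states = spec.state_names

    module_genes = {
        st: [f"{st}MOD{i:03d}" for i in range(spec.genes_per_module)] for st in states
    }
    background = [f"BG{i:04d}" for i in range(spec.n_background_genes)]
    mito = [f"MT-{i}" for i in range(_N_MITO)]
    genes = [g for st in states for g in module_genes[st]] + background + mito
    n_genes = len(genes)
    is_module = np.zeros(n_genes, dtype=bool)
    module_state = np.array([""] * n_genes, dtype=object)
    pos = 0
    for st in states:
        is_module[pos : pos + spec.genes_per_module] = True
        module_state[pos : pos + spec.genes_per_module] = st
        pos += spec.genes_per_module

    cell_states, cell_subjects = [], []
    for subj in range(spec.n_subjects):
        for st in states:
            cell_states += [st] * spec.n_cells_per_state
            cell_subjects += [f"S{subj + 1}"] * spec.n_cells_per_state
    for i in range(spec.n_normal_cells):
        cell_states.append("normal")
        cell_subjects.append(f"S{(i % spec.n_subjects) + 1}")
    n_cells = len(cell_states)
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]

    base = rng.normal(0.0, 1.0, size=n_genes)
    base[is_module] = rng.normal(_MODULE_BASELINE, 0.25, size=int(is_module.sum()))
    subj_names = sorted(set(cell_subjects))
    subj_offsets = {s: rng.normal(0.0, _SUBJECT_SD, size=n_genes) for s in subj_names}
    libs = rng.lognormal(np.log(spec.mean_library_size), _LIBRARY_SIGMA, size=n_cells)

    # graded module: elevation varies across a module's genes (strong markers to
    # weak ones), spanning 0.5x..1.5x of the state's mean elevation
    grade = np.zeros(n_genes)
    pos = 0
    for st in states:
        grade[pos : pos + spec.genes_per_module] = np.linspace(
            1.5, 0.5, num=spec.genes_per_module
        )
        pos += spec.genes_per_module
    elevation = _ELEVATION_SCALE * spec.module_effect * grade

    eta = np.empty((n_genes, n_cells))
    for j in range(n_cells):
        e = base + subj_offsets[cell_subjects[j]]
        st = cell_states[j]
        if st != "normal":
            e = e + np.where(module_state == st, elevation, 0.0)
        eta[:, j] = e
    eta += rng.normal(0.0, _BIO_NOISE_SCALE * spec.noise_sd, size=eta.shape)
    lam = np.exp(eta)
    lam /= lam.sum(axis=0, keepdims=True)
    mean = lam * libs

    if spec.dispersion > 0:
        shape = 1.0 / spec.dispersion
        mean = rng.gamma(shape, mean * spec.dispersion)
    counts = rng.poisson(mean).astype(float)

    expr = GeneExpressionMatrix(genes, cell_ids, counts, layer="counts")
    meta = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "subject_id": cell_subjects,
            "state": cell_states,
            "compartment": ["normal" if s == "normal" else "tumor" for s in cell_states],
        }
    )
    gene_pos = {g: i for i, g in enumerate(genes)}
    strength = {
        st: pd.Series(
            [elevation[gene_pos[g]] for g in module_genes[st]], index=module_genes[st]
        )
        for st in states
    }
    truth = GroundTruth(
        states=pd.Series(cell_states, index=cell_ids, name="state"),
        modules=module_genes,
        background_genes=background,
        module_strength=strength,
    )
    return expr, meta, truth


def _graded_scores(genes: list, strength: pd.Series | None, scale: float = 2.0) -> np.ndarray:
    """Rank-graded positive scores in [1, scale], aligned to module-gene strength.

    Stronger (more highly expressed when elevated) genes get larger scores;
    rounding to one decimal introduces nontrivial score ties.
    """
    n = len(genes)
    if strength is not None:
        order = strength.loc[genes].rank(method="first").to_numpy()  # 1 = weakest
    else:
        order = np.arange(1, n + 1, dtype=float)
    vals = 1.0 + (order - 1.0) / max(n - 1, 1) * (scale - 1.0)
    return np.round(vals, 1)


def generate_signature_library(
    truth: GroundTruth,
    sizes: dict | int | None = None,
    frac_offtarget_noise: float = 0.1,
    seed: int = 0,
) -> list:
    """Targeting and reversal signatures for every state in the ground truth.

    A state's targeting signature up-weights its module genes with graded
    scores plus a fraction ``frac_offtarget_noise`` of random-sign background
    genes; the reversal signature is its negation.  Signatures are annotated
    in ``truth.signatures``.
    """
    if not 0 <= frac_offtarget_noise <= 1:
        raise ValueError("frac_offtarget_noise must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for st in sorted(truth.modules):
        module = truth.modules[st]
        size = len(module)
        if isinstance(sizes, int):
            size = sizes
        elif isinstance(sizes, dict):
            size = sizes.get(st, size)
        if size > len(module) + len(truth.background_genes):
            raise ValueError(f"signature size {size} exceeds available genes")
        n_noise = int(round(frac_offtarget_noise * size))
        n_mod = min(size - n_noise, len(module))
        mod_genes = list(rng.choice(module, size=n_mod, replace=False)) if n_mod else []
        noise_genes = list(
            rng.choice(truth.background_genes, size=size - n_mod, replace=False)
        )
        scores = {}
        if mod_genes:
            graded = _graded_scores(mod_genes, truth.module_strength.get(st))
            for g, s in zip(mod_genes, graded):
                scores[g] = float(s)
        for g in noise_genes:
            scores[g] = float(rng.uniform(0.25, 1.0) * rng.choice([-1.0, 1.0]))
        target = DirectionalSignature(f"target_{st}", pd.Series(scores))
        reversal = target.negated(f"reversal_{st}")
        truth.signatures[target.name] = {"state": st, "direction": "target"}
        truth.signatures[reversal.name] = {"state": st, "direction": "reversal"}
        out += [target, reversal]
    return out


def generate_random_signatures(
    truth: GroundTruth,
    n: int,
    size: int = 40,
    seed: int = 0,
    prefix: str = "noise",
) -> list:
    """Null signatures drawn from background genes with random signed scores."""
    rng = np.random.default_rng(seed)
    if size > len(truth.background_genes):
        raise ValueError("signature size exceeds the background gene pool")
    out = []
    for i in range(n):
        genes = rng.choice(truth.background_genes, size=size, replace=False)
        scores = rng.uniform(0.25, 2.0, size=size) * rng.choice([-1.0, 1.0], size=size)
        name = f"{prefix}{i:02d}"
        out.append(DirectionalSignature(name, pd.Series(scores, index=genes)))
        truth.signatures[name] = {"state": None, "direction": "noise"}
    return out


def generate_de_table(
    truth: GroundTruth,
    n_sig: int = 50,
    effect: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Bulk-style DE table with ``n_sig`` planted large-|logFC| significant genes.

    The remaining genes get near-zero logFC and uniform raw p-values; the
    adjusted p column comes from a BH pass over the whole table, so a
    mean + 2 sd magnitude rule recovers exactly the planted set.
    """
    from statsmodels.stats.multitest import multipletests

    genes = sorted(set(truth.background_genes) | {g for m in truth.modules.values() for g in m})
    if n_sig > len(genes):
        raise ValueError("n_sig exceeds the gene count")
    rng = np.random.default_rng(seed)
    lfc = rng.normal(0.0, 0.08, size=len(genes))
    p = rng.uniform(0.0, 1.0, size=len(genes))
    planted = rng.choice(len(genes), size=n_sig, replace=False)
    signs = np.where(np.arange(n_sig) % 2 == 0, 1.0, -1.0)
    lfc[planted] = signs * (effect + np.abs(rng.normal(0.0, 0.1, size=n_sig)))
    p[planted] = rng.uniform(1e-10, 1e-6, size=n_sig)
    adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"gene": genes, "logFC": lfc, "p": p, "adj_p": adj})
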