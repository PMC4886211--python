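"""Synthetic fermentation datasets with planted two-block latent structure.

The generator emulates the design of a solid-state acetic acid
fermentation (AAF) study: three parallel batches sampled daily over
19 days (day 0 through day 18), ~200 genus-level microbial profiles
(bacteria + fungi) and 88 flavour compounds (2 sugars, 9 organic acids,
18 amino acids, 59 volatiles).  Both blocks share a small number of
joint latent components; each block additionally carries structured
variation of its own, and a set of "core" taxa is planted with strong
loadings so that the full inference chain (O2PLS fit, VIP, correlation
network, core selection, stage statistics) has a known right answer.

Model
-----
Joint scores ``T`` are smooth functions of fermentation day shared across
batches (a late logistic rise tracking acidification, and a
mid-fermentation hump) plus seeded batch-level noise.  The latent
abundance block is ``X* = T W' + T_ox P_ox' + E`` and the flavour block is
``Y = T B C' + T_oy P_oy' + F`` with unit-norm loading columns and
diagonal positive ``B``.  ``X*`` is rendered compositional by a softmax
per sample followed by multinomial count sampling at a fixed sequencing
depth.  The Y-orthogonal component is a raw-material signature that decays
after day 0 (substrate compounds present before fermentation starts), so
the flavour block carries stage-I distinctness that is *not* shared with
the microbial block.

Loading columns of ``W`` are constructed sum-to-zero.  This makes the
softmax invertible by the centered log-ratio transform up to noise, so
the planted joint subspace is recoverable from counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from fermlink.tables import AbundanceTable, FlavourTable, SampleMetadata


class GeneratorError(ValueError):
    """Raised when a latent specification cannot produce a valid dataset."""


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


# flavour panel layout (88 compounds): indices
#   0-1   sugars (raw-material signature only)
#   2-10  organic acids        } joint component 1 (late rise)
#   11-28 amino acids          }
#   29-53 volatiles            }
#   54-87 volatiles            } joint component 2 (mid hump)
_SUGARS = ["fructose", "glucose"]
_ORGANIC_ACIDS = [
    "acetic_acid", "lactic_acid", "citric_acid", "malic_acid", "succinic_acid",
    "tartaric_acid", "oxalic_acid", "pyruvic_acid", "formic_acid",
]
_AMINO_ACIDS = [
    "alanine", "arginine", "aspartate", "cysteine", "glutamate", "glycine",
    "histidine", "isoleucine", "leucine", "lysine", "methionine",
    "phenylalanine", "proline", "serine", "threonine", "tryptophan",
    "tyrosine", "valine",
]
_VOLATILES = (
    [f"alcohol_{i:02d}" for i in range(1, 10)]        # 9 alcohols
    + [f"volacid_{i:02d}" for i in range(1, 9)]       # 8 acids
    + [f"ester_{i:02d}" for i in range(1, 26)]        # 25 esters
    + [f"ketone_{i:02d}" for i in range(1, 5)]        # 4 ketones
    + [f"aldehyde_{i:02d}" for i in range(1, 8)]      # 7 aldehydes
    + ["tetramethylpyrazine", "trimethylpyrazine", "furfural_het"]  # 3 heterocycles
    + [f"other_{i:02d}" for i in range(1, 4)]         # 3 others
)
_VOL_SUBCAT = (
    ["alcohols"] * 9 + ["acids"] * 8 + ["esters"] * 25 + ["ketones"] * 4
    + ["aldehydes"] * 7 + ["heterocycles"] * 3 + ["others"] * 3
)


def default_flavour_panel(q: int) -> tuple[list[str], list[str], list[str]]:
    """Names, categories and subcategories for a q-flavour panel.

    The study layout (q = 88) uses real compound names; other sizes fall
    back to generic identifiers with categories assigned proportionally.
    """
    if q == 88:
        names = _SUGARS + _ORGANIC_ACIDS + _AMINO_ACIDS + _VOLATILES
        cats = (["sugar"] * 2 + ["organic_acid"] * 9 + ["amino_acid"] * 18
                + ["volatile"] * 59)
        subs = [""] * 29 + _VOL_SUBCAT
        return names, cats, subs
    n_sug = max(1, round(q * 2 / 88))
    n_oa = max(1, round(q * 9 / 88))
    n_aa = max(1, round(q * 18 / 88))
    n_vf = q - n_sug - n_oa - n_aa
    if n_vf < 1:
        raise GeneratorError(f"q_flavours={q} too small for a categorized panel")
    names = ([f"sugar_{i:02d}" for i in range(n_sug)]
             + [f"oa_{i:02d}" for i in range(n_oa)]
             + [f"aa_{i:02d}" for i in range(n_aa)]
             + [f"vf_{i:02d}" for i in range(n_vf)])
    cats = (["sugar"] * n_sug + ["organic_acid"] * n_oa
            + ["amino_acid"] * n_aa + ["volatile"] * n_vf)
    subs = [""] * (n_sug + n_oa + n_aa) + ["esters"] * n_vf
    return names, cats, subs


@dataclass
class LatentSpec:
    """Parameters of the planted-truth generator.

    Defaults mirror the study design: 3 batches x 19 daily samples
    (n = 57), 200 genera (100 bacterial + 100 fungal), 88 flavours and a
    7-genus planted core.  ``core_loading_scale`` is the factor by which
    core rows of the joint X-loadings exceed ordinary rows; the default 5
    makes every core genus highly correlated (|rho| > 0.8) with well over
    25 flavours while leaving ordinary genera below that bar.
    """

    n_batches: int = 3
    n_days: int = 18                      # samples per batch = n_days + 1 (day 0 included)
    p_taxa: int = 200
    q_flavours: int = 88
    k_joint: int = 2
    nx_orth: int = 1
    ny_orth: int = 1
    core_indices: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6)
    core_loading_scale: float = 5.0
    noise_sd_x: float = 0.05
    noise_sd_y: float = 0.05
    sequencing_depth: int = 50_000
    seed: int = 0
    # shape of the temporal succession -------------------------------------
    score_scales: tuple[float, ...] = (4.3, 3.6)  # per joint component amplitude (max |score|)
    stage_sharpness: float = 1.5                  # slope (days) of the late logistic rise
    score_noise_sd: float = 0.05                  # batch-level + sample-level score jitter
    # block-specific structure ---------------------------------------------
    orth_x_scale: float = 0.4           # amplitude of X-orthogonal variation
    signature_sugar_scale: float = 12.0  # raw-material signature on sugars
    signature_scale: float = 5.0        # raw-material signature on component-1 flavours
    noncore_loading_bound: float = 0.5  # |W| bound for ordinary taxa (uniform draws)
    inner_b: float = 8.0                # diagonal of the inner regression B

    @property
    def n_samples(self) -> int:
        return self.n_batches * (self.n_days + 1)

    def validate(self) -> None:
        if self.k_joint < 1:
            raise GeneratorError("k_joint must be >= 1")
        if self.k_joint > 4:
            raise GeneratorError("k_joint > 4 not supported by the temporal basis")
        if min(self.n_batches, self.n_days, self.p_taxa, self.q_flavours) < 1:
            raise GeneratorError("n_batches, n_days, p_taxa, q_flavours must be positive")
        core = np.asarray(self.core_indices, dtype=int)
        if core.size and (core.min() < 0 or core.max() >= self.p_taxa):
            raise GeneratorError("core_indices out of range for p_taxa")
        if len(set(self.core_indices)) != len(self.core_indices):
            raise GeneratorError("core_indices contains duplicates")
        for name in ("core_loading_scale", "noise_sd_x", "noise_sd_y",
                     "score_noise_sd", "sequencing_depth"):
            if getattr(self, name) < 0:
                raise GeneratorError(f"{name} must be non-negative")
        if self.core_loading_scale <= 0:
            raise GeneratorError("core_loading_scale must be positive")
        if self.n_samples <= self.k_joint + self.nx_orth + self.ny_orth:
            raise GeneratorError(
                f"n = {self.n_samples} samples cannot support "
                f"{self.k_joint} joint + {self.nx_orth}+{self.ny_orth} orthogonal components"
            )


@dataclass
class SyntheticDataset:
    """A generated dataset plus its ground truth."""

    abundance: AbundanceTable          # multinomial counts, taxa x samples
    flavours: FlavourTable             # non-negative concentrations
    metadata: SampleMetadata
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# score / loading generation
# ---------------------------------------------------------------------------

def _day_curves(day: np.ndarray, spec: LatentSpec) -> np.ndarray:
    """Deterministic per-day shapes of the joint components.

    Component 1 is a late logistic rise (the acidification-driven
    succession); component 2 a mid-fermentation hump; components 3-4, if
    requested, are slow cosine modes.  Later columns are orthogonalized
    against earlier ones so each contributes fresh variance.
    """
    mid = spec.n_days / 2.0
    shapes = [
        _logistic((day - (mid + 0.5)) / spec.stage_sharpness),
        np.exp(-(((day - 0.39 * spec.n_days) / (0.19 * spec.n_days + 0.08)) ** 4)),
        np.cos(np.pi * day / max(spec.n_days, 1)),
        np.cos(2 * np.pi * day / max(spec.n_days, 1)),
    ]
    cols = []
    for k in range(spec.k_joint):
        v = shapes[k] - shapes[k].mean()
        for u in cols:
            v = v - (v @ u) / (u @ u) * u
        cols.append(v)
    return np.column_stack(cols)


def generate_scores(spec: LatentSpec) -> dict:
    """Joint and orthogonal score matrices for the given specification.

    Returns a dict with ``T`` (n x k_joint), ``T_orth_x`` (n x nx) and
    ``T_orth_y`` (n x ny).  Joint columns are smooth functions of day
    shared across batches plus seeded batch-level (and smaller
    sample-level) noise, scaled to the per-component amplitude in
    ``score_scales``.  Orthogonal scores have zero centered inner product
    with the joint scores.  The Y-orthogonal score is a raw-material
    signature decaying after day 0; the X-orthogonal scores are seeded
    Gaussian draws.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 0])
    n = spec.n_samples
    day = np.tile(np.arange(spec.n_days + 1), spec.n_batches).astype(float)
    batch = np.repeat(np.arange(spec.n_batches), spec.n_days + 1)

    T = _day_curves(day, spec)
    T = (T
         + rng.normal(0.0, spec.score_noise_sd, (spec.n_batches, spec.k_joint))[batch]
         + rng.normal(0.0, spec.score_noise_sd / 2.0, (n, spec.k_joint)))
    T -= T.mean(axis=0)
    scales = np.asarray(spec.score_scales, dtype=float)
    if scales.size < spec.k_joint:
        scales = np.concatenate([scales, np.full(spec.k_joint - scales.size, scales[-1])])
    maxabs = np.abs(T).max(axis=0)
    maxabs[maxabs == 0] = 1.0
    T *= scales[: spec.k_joint] / maxabs

    def _orthogonalize(S: np.ndarray) -> np.ndarray:
        S = S - S.mean(axis=0)
        S = S - T @ np.linalg.lstsq(T, S, rcond=None)[0]
        mx = np.abs(S).max(axis=0)
        mx[mx == 0] = 1.0
        return S / mx

    T_orth_x = np.empty((n, 0))
    if spec.nx_orth:
        T_orth_x = _orthogonalize(rng.normal(0.0, 1.0, (n, spec.nx_orth)))
    T_orth_y = np.empty((n, 0))
    if spec.ny_orth:
        sig = (np.exp(-day / 0.6)[:, None]
               + rng.normal(0.0, 0.05, (n, spec.ny_orth)))
        T_orth_y = _orthogonalize(sig)
    return {"T": T, "T_orth_x": T_orth_x, "T_orth_y": T_orth_y,
            "day": day.astype(int), "batch": batch}


def generate_loadings(spec: LatentSpec) -> dict:
    """Joint and orthogonal loading matrices with planted core structure.

    ``W`` (p x k) is sparse for ordinary taxa (bounded uniform draws, 30 %
    density) while each core row carries one dominant entry scaled by
    ``core_loading_scale``; core rows are guaranteed to be the rows of
    largest Euclidean norm, otherwise a planted-truth violation is raised.
    ``W`` columns are constructed sum-to-zero, then unit-normalized.
    ``C`` (q x k) assigns organic acids, amino acids and the first block
    of volatiles to component 1 and the remaining volatiles to component
    2; sugars carry no joint signal (they belong to the raw-material
    signature).  All loading columns have unit norm.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 1])
    p, q, k = spec.p_taxa, spec.q_flavours, spec.k_joint
    core = np.asarray(spec.core_indices, dtype=int)

    W = rng.uniform(-spec.noncore_loading_bound, spec.noncore_loading_bound, (p, k))
    W[rng.random((p, k)) < 0.7] = 0.0
    if core.size:
        W[core] = 0.0
        # spread core taxa across joint components (ceil-balanced)
        core_comp = np.array([i % k for i in range(core.size)])
        core_comp.sort()
        main = (rng.choice([-1.0, 1.0], core.size)
                * (1.0 + 0.2 * np.abs(rng.normal(0.0, 1.0, core.size)))
                * spec.core_loading_scale)
        W[core, core_comp] = main
        if k > 1:
            for i, g in enumerate(core):
                others = [a for a in range(k) if a != core_comp[i]]
                W[g, others] = 0.05 * spec.core_loading_scale * rng.normal(0.0, 1.0, len(others))
    W -= W.mean(axis=0)
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    W /= norms

    if core.size:
        row_norm = np.linalg.norm(W, axis=1)
        rank = np.argsort(-row_norm)
        top = set(rank[: core.size].tolist())
        if top != set(core.tolist()):
            raise GeneratorError(
                "planted-truth violation: a non-core row outranks a core row in "
                "loading norm; increase core_loading_scale"
            )

    # flavour loadings -----------------------------------------------------
    # Sugars are raw-material compounds and carry no joint signal.  The
    # remaining flavours are split ~60/40 between the first two joint
    # components *within every category*, so each component's flavour set
    # spans organic acids, amino acids and volatiles alike.
    n_sig_only = 2 if q >= 10 else 0
    _, cats, _ = default_flavour_panel(q)
    comp_of = np.zeros(q, dtype=int)
    if k > 1:
        for cat in ("organic_acid", "amino_acid", "volatile"):
            idx = np.flatnonzero((np.asarray(cats) == cat)
                                 & (np.arange(q) >= n_sig_only))
            cut = int(np.ceil(idx.size * 0.6))
            comp_of[idx[cut:]] = 1
    C = 0.03 * rng.normal(0.0, 1.0, (q, k))
    main_c = (rng.choice([-1.0, 1.0], q)
              * (1.0 + 0.2 * np.abs(rng.normal(0.0, 1.0, q))))
    C[np.arange(q), np.minimum(comp_of, k - 1)] = main_c
    if n_sig_only:
        C[:n_sig_only] = 0.0
    C /= np.linalg.norm(C, axis=0)

    P_orth_x = np.empty((p, 0))
    if spec.nx_orth:
        P_orth_x = rng.normal(0.0, 1.0, (p, spec.nx_orth))
        P_orth_x -= P_orth_x.mean(axis=0)
        P_orth_x /= np.linalg.norm(P_orth_x, axis=0)

    P_orth_y = np.empty((q, 0))
    if spec.ny_orth:
        P_orth_y = np.zeros((q, spec.ny_orth))
        if n_sig_only:
            P_orth_y[:n_sig_only, 0] = spec.signature_sugar_scale
        c1 = np.flatnonzero((comp_of == 0) & (np.arange(q) >= n_sig_only))
        P_orth_y[c1, 0] = (spec.signature_scale
                           * rng.choice([-1.0, 1.0], c1.size)
                           * rng.uniform(0.5, 1.0, c1.size))
        for j in range(1, spec.ny_orth):
            v = rng.normal(0.0, 1.0, q)
            P_orth_y[:, j] = v / np.linalg.norm(v)

    return {"W": W, "C": C, "P_orth_x": P_orth_x, "P_orth_y": P_orth_y,
            "flavour_component": comp_of}


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def assemble_dataset(spec: LatentSpec) -> SyntheticDataset:
    """Generate a complete abundance + flavour + metadata triple with truth.

    The latent abundance block ``X* = T W' + T_ox P_ox' + noise`` is
    rendered compositional by a per-sample softmax and multinomial
    sampling at ``sequencing_depth``; the flavour block
    ``Y = T B C' + T_oy P_oy' + noise`` is shifted to be non-negative.
    The returned truth dict records scores, loadings, the core set and
    the stage partition (stage I = day 0, II = days 1-9, III = days 10-18
    on the default 18-day design).
    """
    spec.validate()
    scores = generate_scores(spec)
    loadings = generate_loadings(spec)
    rng = np.random.default_rng([spec.seed, 2])

    T, Tox, Toy = scores["T"], scores["T_orth_x"], scores["T_orth_y"]
    W, C = loadings["W"], loadings["C"]
    Pox, Poy = loadings["P_orth_x"], loadings["P_orth_y"]
    day, batch = scores["day"], scores["batch"]
    n, p, q = spec.n_samples, spec.p_taxa, spec.q_flavours

    B = np.eye(spec.k_joint) * spec.inner_b
    X_lat = T @ W.T + rng.normal(0.0, spec.noise_sd_x, (n, p))
    if Tox.size:
        X_lat += spec.orth_x_scale * Tox @ Pox.T
    Y = T @ B @ C.T + rng.normal(0.0, spec.noise_sd_y, (n, q))
    if Toy.size:
        Y += Toy @ Poy.T
    Y = Y - Y.min(axis=0)                      # concentrations are non-negative

    expX = np.exp(X_lat - X_lat.max(axis=1, keepdims=True))
    probs = expX / expX.sum(axis=1, keepdims=True)
    counts = np.empty((n, p), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(spec.sequencing_depth, probs[i])

    # identifiers ----------------------------------------------------------
    n_bact = spec.p_taxa // 2
    taxa = ([f"g_bact_{i:03d}" for i in range(n_bact)]
            + [f"g_fung_{i:03d}" for i in range(spec.p_taxa - n_bact)])
    kingdom = pd.Series(
        ["bacteria"] * n_bact + ["fungi"] * (spec.p_taxa - n_bact), index=taxa,
    )
    fl_names, fl_cats, fl_subs = default_flavour_panel(q)
    samples = [f"b{b + 1}_d{d:02d}" for b, d in zip(batch, day)]

    abundance = AbundanceTable(
        pd.DataFrame(counts.T, index=taxa, columns=samples), kingdom,
    )
    flavours = FlavourTable(
        pd.DataFrame(Y.T, index=fl_names, columns=samples),
        pd.Series(fl_cats, index=fl_names),
        pd.Series(fl_subs, index=fl_names),
    )

    # stage truth: day 0 | early | late, split at the score-1 midpoint
    stage_break = int(np.ceil(spec.n_days / 2)) + 1   # day 10 on the default design
    stage = np.where(day == 0, "I", np.where(day < stage_break, "II", "III"))
    acidity = 4.5 * _logistic((day - 0.44 * spec.n_days) / 2.5) + 0.5 \
        + rng.normal(0.0, 0.08, n)
    alcohol = 3.5 * _logistic(-(day - 0.33 * spec.n_days) / 2.0) + 0.2 \
        + rng.normal(0.0, 0.08, n)
    temperature = 33.0 + rng.normal(0.0, 1.0, n)     # deliberately uncorrelated
    metadata = SampleMetadata(pd.DataFrame(
        {
            "day": day,
            "batch": [f"batch_{b + 1}" for b in batch],
            "stage": stage,
            "titratable_acidity": acidity,
            "alcohol": alcohol,
            "temperature": temperature,
        },
        index=pd.Index(samples, name="sample_id"),
    ))

    truth = {
        "T": T, "W": W, "C": C, "B": B,
        "T_orth_x": Tox, "P_orth_x": Pox,
        "T_orth_y": Toy, "P_orth_y": Poy,
        "core_indices": tuple(int(i) for i in spec.core_indices),
        "core_taxa": [taxa[i] for i in spec.core_indices],
        "latent_probs": probs,
        "flavour_component": loadings["flavour_component"],
        "stage_breaks": (0, stage_break),
        "spec": asdict(spec),
    }
    return SyntheticDataset(abundance, flavours, metadata, truth)
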