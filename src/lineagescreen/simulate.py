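"""Synthetic screens with known ground truth.

Every generator returns its truth object alongside the data, so tests can
score estimates against designed effects without re-inferring anything.

The bulk generator emulates a two-arm FACS screen: a shared log-normal pool
of guide abundances, a gene-level log2 effect applied to population B only
in the Cas9 arm, and multinomial read sampling per replicate at a fixed
depth. The single-cell generator emulates a Perturb-seq run: one true guide
per cell, negative-binomial guide UMIs diluted by an ambient multinomial
mixture, cell-type membership following designed odds ratios against NTC
cells, QC covariates with a designed fraction of failing cells, and a noisy
1-D branching manifold embedding with ground-truth pseudotime.

These are fixtures-by-construction, not transcriptome simulators: expression
content is only rich enough to exercise QC, PCA and pseudotime.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bulk_screen import NTC_GENE, GuideLibrary, ScreenCountMatrix

__all__ = [
    "BulkSimTruth",
    "ScSimTruth",
    "ScSim",
    "simulate_bulk_screen",
    "simulate_sc_dataset",
    "simulate_manifold",
]


@dataclass
class BulkSimTruth:
    """Design of a synthetic two-arm sorted-population screen."""

    n_genes: int = 200
    guides_per_gene: int = 4
    n_ntc: int = 200
    #: gene label -> log2 shift of population-B abundance in the Cas9 arm
    effects: dict = field(default_factory=dict)
    depth: int = 2_000_000
    n_replicates: int = 2
    pool_sigma: float = 1.0
    population_a: str = "multipotent"
    population_b: str = "differentiated"
    system: str = "exvivo-myeloid"
    seed: int = 0

    def gene_names(self) -> list[str]:
        return [f"gene{i:04d}" for i in range(1, self.n_genes + 1)]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def simulate_bulk_screen(truth: BulkSimTruth) -> tuple[ScreenCountMatrix, BulkSimTruth]:
    """Draw a guide x sample count matrix under the designed truth.

    Pool abundances are log-normal(0, pool_sigma) per guide and shared by
    both arms; the Cas9-arm population-B abundance of gene g's guides is
    multiplied by 2**delta_g; reads are multinomial at ``depth`` per
    replicate. NTC guides always have delta = 0.
    """
    if truth.depth <= 0:
        raise ValueError("depth must be positive")
    unknown = set(truth.effects) - set(truth.gene_names())
    if unknown:
        raise ValueError(f"effects reference unknown genes: {sorted(unknown)}")
    rng = np.random.default_rng(truth.seed)
    genes = truth.gene_names()
    guide_ids, targets = [], []
    for g in genes:
        for j in range(1, truth.guides_per_gene + 1):
            guide_ids.append(f"{g}_g{j}")
            targets.append(g)
    for j in range(1, truth.n_ntc + 1):
        guide_ids.append(f"NTC_{j:04d}")
        targets.append(NTC_GENE)
    lib = GuideLibrary(
        pd.DataFrame(
            {
                "guide_id": guide_ids,
                "target_gene": targets,
                "is_ntc": [t == NTC_GENE for t in targets],
            }
        )
    )
    abund = rng.lognormal(mean=0.0, sigma=truth.pool_sigma, size=len(guide_ids))
    delta = np.array([truth.effects.get(t, 0.0) for t in targets])
    cols, meta = {}, []
    for cas9 in (True, False):
        for pop in (truth.population_a, truth.population_b):
            w = abund.copy()
            if cas9 and pop == truth.population_b:
                w = w * (2.0 ** delta)
            probs = w / w.sum()
            for rep in range(1, truth.n_replicates + 1):
                sid = f"{pop}.{'cas9' if cas9 else 'noncas9'}.r{rep}"
                cols[sid] = rng.multinomial(truth.depth, probs)
                meta.append(
                    {"sample_id": sid, "population": pop, "cas9": cas9,
                     "system": truth.system, "replicate": f"r{rep}"}
                )
    counts = pd.DataFrame(cols, index=pd.Index(guide_ids, name="guide_id"))
    scm = ScreenCountMatrix(counts=counts, library=lib, samples=pd.DataFrame(meta))
    return scm, truth


# ---------------------------------------------------------------------------
# single-cell generator
# ---------------------------------------------------------------------------

@dataclass
class ScSimTruth:
    """Design of a synthetic Perturb-seq dataset.

    ``targets`` maps a target gene to its per-cell-type odds ratio versus
    NTC cells (types omitted from the mapping keep odds ratio 1); membership
    probabilities are baseline probabilities reweighted by the odds ratios
    and renormalized, which yields exactly the designed OR when a single
    type is modified.
    """

    cell_types: tuple = ("HSC_MPP", "GMP", "MEP", "Mono")
    baseline_probs: tuple = (0.25, 0.25, 0.25, 0.25)
    #: target gene -> {cell_type: designed odds ratio vs NTC}
    targets: dict = field(default_factory=dict)
    guides_per_target: int = 2
    n_ntc_guides: int = 2
    cells_per_target: int = 1000
    cells_per_ntc_guide: int = 1000
    ambient_rate: float = 0.1
    nb_mean: float = 20.0
    nb_dispersion: float = 0.5
    qc_fail_fraction: float = 0.07
    n_pcs: int = 8
    embed_noise_sd: float = 0.05
    sample_id: str = "batch1"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ScSim:
    """Synthetic Perturb-seq bundle: per-cell metadata (including the true
    guide, cell type, QC covariates, latent pseudotime and branch), the
    cells x guides UMI matrix, the PCA-like embedding, the guide library and
    the truth object."""

    cells: pd.DataFrame
    guide_umis: pd.DataFrame
    embedding: np.ndarray
    library: GuideLibrary
    truth: ScSimTruth


def _branch_curve(u: np.ndarray, branch_sign: np.ndarray, n_pcs: int) -> np.ndarray:
    """Smooth injective map of latent time into n_pcs dimensions. Branches
    are mirror images in one coordinate after the split at u = 0.4, so both
    have identical arc-length speed."""
    sep = np.clip((u - 0.4) / 0.6, 0.0, None) ** 2
    cols = [
        np.cos(1.5 * np.pi * u),
        np.sin(1.5 * np.pi * u),
        2.0 * u,
        0.8 * branch_sign * sep,
    ]
    for d in range(4, n_pcs):
        cols.append(0.3 * np.cos(2.0 * np.pi * u * (d - 2) / 3.0 + d))
    return np.column_stack(cols[:n_pcs])


def simulate_manifold(
    n_ref: int,
    n_query: int,
    n_pcs: int = 8,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> dict:
    """Reference and query cells on the same noisy 1-D branching manifold.

    Returns a dict with ``ref_embedding``/``query_embedding`` (arrays),
    ``ref_time``/``query_time`` (latent pseudotime in [0, 1]) and
    ``ref_branch``/``query_branch`` labels.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for name, n in (("ref", n_ref), ("query", n_query)):
        u = rng.uniform(0.0, 1.0, size=n)
        sign = rng.choice([-1.0, 1.0], size=n)
        x = _branch_curve(u, sign, n_pcs)
        x = x + rng.normal(0.0, noise_sd, size=x.shape)
        branch = np.where(u < 0.4, "trunk", np.where(sign > 0, "branchA", "branchB"))
        out[f"{name}_embedding"] = x
        out[f"{name}_time"] = u
        out[f"{name}_branch"] = branch
    return out


def simulate_sc_dataset(truth: ScSimTruth) -> ScSim:
    """Draw a synthetic Perturb-seq dataset under the designed truth."""
    if not 0.0 <= truth.ambient_rate < 1.0:
        raise ValueError("ambient_rate must lie in [0, 1)")
    p0 = np.asarray(truth.baseline_probs, dtype=float)
    if len(p0) != len(truth.cell_types) or not np.isclose(p0.sum(), 1.0):
        raise ValueError("baseline_probs must match cell_types and sum to 1")
    rng = np.random.default_rng(truth.seed)
    genes = sorted(truth.targets)
    guide_ids, guide_targets = [], []
    for g in genes:
        for j in range(1, truth.guides_per_target + 1):
            guide_ids.append(f"{g}_g{j}")
            guide_targets.append(g)
    for j in range(1, truth.n_ntc_guides + 1):
        guide_ids.append(f"NTC_{j:02d}")
        guide_targets.append(NTC_GENE)
    lib = GuideLibrary(
        pd.DataFrame(
            {
                "guide_id": guide_ids,
                "target_gene": guide_targets,
                "is_ntc": [t == NTC_GENE for t in guide_targets],
            }
        )
    )
    # per-guide cell budget
    cells_per_guide = {}
    for g, t in zip(guide_ids, guide_targets):
        if t == NTC_GENE:
            cells_per_guide[g] = truth.cells_per_ntc_guide
        else:
            cells_per_guide[g] = truth.cells_per_target // truth.guides_per_target
    # cell-type membership probabilities per target
    probs_by_target = {NTC_GENE: p0}
    for g in genes:
        rho = np.array([truth.targets[g].get(ct, 1.0) for ct in truth.cell_types])
        w = p0 * rho
        probs_by_target[g] = w / w.sum()

    n_cells = sum(cells_per_guide.values())
    true_guide = np.repeat(
        list(cells_per_guide), [cells_per_guide[g] for g in cells_per_guide]
    )
    perm = rng.permutation(n_cells)
    true_guide = np.asarray(true_guide)[perm]
    target_of = dict(zip(guide_ids, guide_targets))
    true_target = np.array([target_of[g] for g in true_guide])

    cell_type = np.empty(n_cells, dtype=object)
    for t, probs in probs_by_target.items():
        mask = true_target == t
        if mask.any():
            draws = rng.choice(len(truth.cell_types), size=mask.sum(), p=probs)
            cell_type[mask] = np.asarray(truth.cell_types, dtype=object)[draws]

    # guide UMIs: true-guide NB count plus ambient multinomial contamination
    r = 1.0 / truth.nb_dispersion
    p_nb = r / (r + truth.nb_mean)
    own = np.maximum(1, rng.negative_binomial(r, p_nb, size=n_cells))
    umis = np.zeros((n_cells, len(guide_ids)), dtype=np.int64)
    gidx = {g: i for i, g in enumerate(guide_ids)}
    umis[np.arange(n_cells), [gidx[g] for g in true_guide]] = own
    if truth.ambient_rate > 0:
        lam = truth.nb_mean * truth.ambient_rate / (1.0 - truth.ambient_rate)
        ambient_total = rng.poisson(lam, size=n_cells)
        umis += rng.multinomial(
            ambient_total, np.full(len(guide_ids), 1.0 / len(guide_ids))
        )

    # QC covariates: good cells pass the adaptive thresholds by design;
    # failing cells split between a low-depth mode and a high-mito mode
    fail = rng.random(n_cells) < truth.qc_fail_fraction
    n_umis = np.where(
        fail, rng.lognormal(np.log(800.0), 0.3, n_cells),
        rng.lognormal(np.log(10_000.0), 0.25, n_cells),
    )
    fail_mode_mito = fail & (rng.random(n_cells) < 0.5)
    n_umis[fail_mode_mito] = rng.lognormal(np.log(10_000.0), 0.25, int(fail_mode_mito.sum()))
    n_umis = np.round(n_umis).astype(np.int64)
    n_genes = np.minimum(n_umis, np.round(0.35 * n_umis).astype(np.int64) + 1)
    pct_mito = 0.10 * rng.beta(2.0, 5.0, n_cells)
    pct_mito[fail_mode_mito] = rng.uniform(0.15, 0.5, int(fail_mode_mito.sum()))

    # latent trajectory + embedding
    u = rng.uniform(0.0, 1.0, n_cells)
    sign = rng.choice([-1.0, 1.0], size=n_cells)
    branch = np.where(u < 0.4, "trunk", np.where(sign > 0, "branchA", "branchB"))
    emb = _branch_curve(u, sign, truth.n_pcs)
    emb = emb + rng.normal(0.0, truth.embed_noise_sd, size=emb.shape)

    cell_ids = [f"cell{i:06d}" for i in range(1, n_cells + 1)]
    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "sample_id": truth.sample_id,
            "true_guide": true_guide,
            "true_target": true_target,
            "cell_type": cell_type,
            "n_umis": n_umis,
            "n_genes": n_genes,
            "pct_mito": pct_mito,
            "latent_pseudotime": u,
            "branch": branch,
            "qc_fail": fail,
        }
    )
    guide_umis = pd.DataFrame(
        umis, index=pd.Index(cell_ids, name="cell_id"), columns=guide_ids
    )
    return ScSim(cells=cells, guide_umis=guide_umis, embedding=emb,
                 library=lib, truth=truth)
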