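"""Generative counterpart of the SRM: draw random effects and outcomes."""

from __future__ import annotations

import numpy as np

from ..network_data import AllocationRecord, AllocationSet, BinaryLayer
from .design import SRMDesign
from .likelihood import softmax
from .model import linear_predictor
from .spec import SRMParameters


def draw_sender_receiver_effects(
    n: int,
    sigma_s: float,
    sigma_r: float,
    rho_gr: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated (s_i, r_i) pairs: the generalised-reciprocity block."""
    if abs(rho_gr) > 1:
        raise ValueError("rho_gr must lie in [-1, 1]")
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    s = sigma_s * z1
    r = sigma_r * (rho_gr * z1 + np.sqrt(1.0 - rho_gr**2) * z2)
    return s, r


def draw_dyad_effects(
    n_pairs: int,
    sigma_d: float,
    rho_dd: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated (d_ij, d_ji) pairs: the dyadic-reciprocity block."""
    if abs(rho_dd) > 1:
        raise ValueError("rho_dd must lie in [-1, 1]")
    z1 = rng.standard_normal(n_pairs)
    z2 = rng.standard_normal(n_pairs)
    d_ij = sigma_d * z1
    d_ji = sigma_d * (rho_dd * z1 + np.sqrt(1.0 - rho_dd**2) * z2)
    return d_ij, d_ji


def simulate_layer(
    design: SRMDesign,
    params: SRMParameters,
    seed: int | np.random.Generator,
    layer_name: str = "simulated",
    budgets: np.ndarray | int | None = None,
    coin_value: int = 1000,
):
    """Draw one outcome layer from the SRM generative process.

    Random effects are drawn from their multivariate normals, scores
    assembled, and outcomes sampled: a BinaryLayer for the bernoulli family
    or an AllocationSet (requires ``budgets``) for the multinomial family.
    Reproducible under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = design
    s_all, r_all = draw_sender_receiver_effects(
        d.n, params.sigma_s, params.sigma_r, params.rho_gr, rng
    )
    s = s_all[d.focal_idx]
    dyad = np.zeros((d.n_f, d.n))
    if params.sigma_d > 0:
        iu, ju = np.triu_indices(d.n, k=1)
        d_ij, d_ji = draw_dyad_effects(len(iu), params.sigma_d, params.rho_dd, rng)
        D = np.zeros((d.n, d.n))
        D[iu, ju] = d_ij
        D[ju, iu] = d_ji
        dyad = D[d.focal_idx, :]
    pred = linear_predictor(d, params, s=s, r=r_all, d=dyad)
    eta = pred["eta"]

    if d.spec.outcome_kind == "bernoulli":
        prob = 1.0 / (1.0 + np.exp(-eta))
        y = (rng.uniform(size=eta.shape) < prob).astype(np.int8)
        adj = np.zeros((d.n, d.n), dtype=np.int8)
        adj[d.focal_idx, :] = np.where(d.mask, y, 0)
        return BinaryLayer(layer_name, d.roster, adj, focal_ids=d.focal_ids)

    if budgets is None:
        raise ValueError("multinomial simulation needs budgets")
    budgets = np.broadcast_to(np.asarray(budgets, dtype=int), (d.n_f,))
    probs = softmax(eta, axis=1)
    records = []
    for k, fid in enumerate(d.focal_ids):
        counts = rng.multinomial(budgets[k], probs[k])
        nonzero = {d.roster.ids[j]: int(c) for j, c in enumerate(counts) if c}
        if fid not in nonzero:
            nonzero[fid] = 0
        records.append(
            AllocationRecord(
                game=layer_name,
                focal_id=fid,
                counts=nonzero,
                budget=int(budgets[k]),
                coin_value=coin_value,
            )
        )
    return AllocationSet(layer_name, d.roster, records)
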