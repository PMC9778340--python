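"""Penetrance-model simulator for case-control epistasis data.

One k-order interaction (k in [2, 8]) is planted among independent noise
SNPs.  The penetrance table assigns each of the 3^k genotype combinations a
disease probability built from per-locus risk factors e_j(g) = 1 + theta * g
(risk rises with minor-allele dose):

    multiplicative : f(g) = b * prod_j e_j(g_j)
    additive       : f(g) = b * sum_j  e_j(g_j)
    threshold      : f(g) = b * (1 + theta * [sum_j g_j >= k])

with baseline b and clipping to [0, 1] (a warning is issued when clipping is
active, since it distorts the model class).  theta is solved by a
one-dimensional root search so the realized broad-sense heritability

    h^2 = sum_g P(g) (f(g) - K)^2 / (K (1 - K)),   K = sum_g P(g) f(g)

matches the requested target within 1e-3, with genotype probabilities P(g)
from Hardy-Weinberg equilibrium and linkage equilibrium across loci.

Samples are drawn by rejection: causal genotypes per HWE, phenotype
Bernoulli(f(g)), until the case and control quotas are met exactly.  Noise
SNPs are independent HWE draws at minor-allele frequencies uniform in a
configurable range.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .genotype_io import GenotypeDataset

__all__ = [
    "MODEL_CLASSES",
    "PenetranceModel",
    "SimulatedTruth",
    "genotype_probabilities",
    "realized_heritability",
    "build_penetrance",
    "generate_dataset",
    "write_truth_json",
    "read_truth_json",
]

MODEL_CLASSES = ("additive", "multiplicative", "threshold")

#: heritability-matching tolerance for the theta search
_H2_TOL = 1e-3
_THETA_MAX = 1e9


@dataclass
class PenetranceModel:
    """An order-k penetrance table over 3^k genotype combinations.

    ``table`` is flat, indexed by the radix code sum_j g_j * 3^j (locus 0 is
    the least significant digit).  ``prevalence`` and ``heritability`` are
    the realized population values implied by the table and HWE genotype
    probabilities at ``mafs``.
    """

    order: int
    mafs: tuple[float, ...]
    table: np.ndarray
    model_class: str
    prevalence: float
    heritability: float
    theta: float
    baseline: float

    def __post_init__(self) -> None:
        if not 2 <= self.order <= 8:
            raise ValueError("order must be in [2, 8]")
        if len(self.mafs) != self.order:
            raise ValueError("need one MAF per locus")
        if any(not 0.0 < q <= 0.5 for q in self.mafs):
            raise ValueError("MAFs must lie in (0, 0.5]")
        t = np.asarray(self.table, dtype=float)
        if t.shape != (3**self.order,):
            raise ValueError(f"table must have 3^{self.order} entries")
        if (t < 0).any() or (t > 1).any():
            raise ValueError("penetrances must lie in [0, 1]")
        self.table = t

    def penetrance(self, genotypes: np.ndarray) -> np.ndarray:
        """Penetrance for an (n, k) array of genotype rows."""
        weights = 3 ** np.arange(self.order, dtype=np.int64)
        codes = np.asarray(genotypes, dtype=np.int64) @ weights
        return self.table[codes]


@dataclass
class SimulatedTruth:
    """Ground truth of one simulated dataset."""

    causal_snps: frozenset[int]
    causal_ids: tuple[str, ...]
    order: int
    model_class: str
    heritability: float
    prevalence: float
    seed: int


def genotype_probabilities(mafs) -> np.ndarray:
    """Joint HWE genotype probabilities over 3^k combinations (radix order)."""
    probs = np.ones(1)
    for q in mafs:
        locus = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        probs = np.outer(locus, probs).ravel()  # digit for this locus gets the next stride
    return probs


def _genotype_digits(order: int) -> np.ndarray:
    codes = np.arange(3**order)[:, None]
    return (codes // 3 ** np.arange(order)) % 3


def _raw_scores(model_class: str, order: int, theta: float) -> np.ndarray:
    digits = _genotype_digits(order)
    if model_class == "multiplicative":
        return np.prod(1.0 + theta * digits, axis=1)
    if model_class == "additive":
        return np.sum(1.0 + theta * digits, axis=1)
    if model_class == "threshold":
        return 1.0 + theta * (digits.sum(axis=1) >= order)
    raise ValueError(f"unknown model class {model_class!r}; use one of {MODEL_CLASSES}")


def _table_for(model_class: str, order: int, theta: float, baseline: float) -> np.ndarray:
    return np.clip(baseline * _raw_scores(model_class, order, theta), 0.0, 1.0)


def realized_heritability(table: np.ndarray, probs: np.ndarray) -> tuple[float, float]:
    """(prevalence, h^2) of a penetrance table under the genotype distribution."""
    table = np.asarray(table, dtype=float)
    k = float(probs @ table)
    if k <= 0.0 or k >= 1.0:
        return k, 0.0
    h2 = float(probs @ (table - k) ** 2 / (k * (1.0 - k)))
    return k, h2


def build_penetrance(
    model_class: str,
    order: int,
    mafs,
    target_heritability: float,
    baseline: float = 0.1,
) -> PenetranceModel:
    """Solve for theta so the realized heritability matches the target.

    ``mafs`` may be a scalar (shared by all loci) or a length-k sequence.
    Raises when the target is unattainable for the given class/MAFs/baseline,
    naming the feasible bound found by the search.
    """
    if np.isscalar(mafs):
        mafs = (float(mafs),) * order
    mafs = tuple(float(q) for q in mafs)
    if target_heritability < 0:
        raise ValueError("target heritability must be non-negative")
    if not 0.0 < baseline <= 1.0:
        raise ValueError("baseline penetrance must lie in (0, 1]")
    probs = genotype_probabilities(mafs)

    def h2_at(theta: float) -> float:
        return realized_heritability(_table_for(model_class, order, theta, baseline), probs)[1]

    if target_heritability == 0.0:
        theta = 0.0
    else:
        hi = 1.0
        while h2_at(hi) < target_heritability and hi < _THETA_MAX:
            hi *= 2.0
        if h2_at(hi) < target_heritability:
            raise ValueError(
                f"heritability {target_heritability} unattainable for "
                f"{model_class} order {order} at MAFs {mafs} (feasible up to "
                f"~{h2_at(hi):.4f})"
            )
        theta = float(
            optimize.brentq(
                lambda t: h2_at(t) - target_heritability, 0.0, hi, xtol=1e-12, rtol=1e-14
            )
        )
    raw = baseline * _raw_scores(model_class, order, theta)
    if (raw > 1.0).any():
        warnings.warn(
            f"penetrance clipping active for {model_class} order {order} "
            f"(theta={theta:.4g}); the model class is distorted at clipped cells",
            stacklevel=2,
        )
    table = np.clip(raw, 0.0, 1.0)
    prevalence, h2 = realized_heritability(table, probs)
    if abs(h2 - target_heritability) > _H2_TOL:
        raise ValueError(
            f"theta search failed to match heritability: got {h2:.5f}, "
            f"target {target_heritability:.5f}"
        )
    return PenetranceModel(
        order=order,
        mafs=mafs,
        table=table,
        model_class=model_class,
        prevalence=prevalence,
        heritability=h2,
        theta=theta,
        baseline=baseline,
    )


def _draw_hwe(rng: np.random.Generator, mafs: np.ndarray, n: int) -> np.ndarray:
    """(n, len(mafs)) genotype draws under HWE, one MAF per column."""
    q = np.asarray(mafs, dtype=float)
    p0 = (1 - q) ** 2
    p01 = p0 + 2 * q * (1 - q)
    u = rng.random((n, q.shape[0]))
    return ((u > p0) .astype(np.int8) + (u > p01).astype(np.int8))


def generate_dataset(
    model: PenetranceModel,
    n_snps: int,
    n_cases: int,
    n_controls: int,
    noise_maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> tuple[GenotypeDataset, SimulatedTruth]:
    """Simulate a balanced-or-not case-control dataset with one planted model.

    Causal SNPs are placed at randomized positions (ids ``M0..``), noise SNPs
    (ids ``N0..``) fill the rest.  Case/control counts are exact; sample rows
    appear in the order the rejection sampler accepted them.
    """
    k = model.order
    if n_snps < k:
        raise ValueError("n_snps must be at least the model order")
    if n_cases < 0 or n_controls < 0 or n_cases + n_controls == 0:
        raise ValueError("need a positive number of samples")
    if model.table.max() == 0.0 and n_cases > 0:
        raise ValueError("penetrance table is all-zero; no cases can be generated")
    if model.table.min() == 1.0 and n_controls > 0:
        raise ValueError("penetrance table is all-one; no controls can be generated")
    rng = np.random.default_rng(seed)
    n_total = n_cases + n_controls
    probs = genotype_probabilities(model.mafs)
    digits = _genotype_digits(k).astype(np.int8)

    got_cases = 0
    got_controls = 0
    rows: list[np.ndarray] = []
    pheno: list[int] = []
    batch = max(4 * n_total, 1000)
    guard = 0
    while got_cases < n_cases or got_controls < n_controls:
        guard += 1
        if guard > 10_000:
            raise RuntimeError("rejection sampling failed to fill case/control quotas")
        codes = rng.choice(3**k, size=batch, p=probs)
        f = model.table[codes]
        is_case = rng.random(batch) < f
        for code, case in zip(codes, is_case):
            if case and got_cases < n_cases:
                rows.append(digits[code])
                pheno.append(1)
                got_cases += 1
            elif not case and got_controls < n_controls:
                rows.append(digits[code])
                pheno.append(0)
                got_controls += 1
            if got_cases >= n_cases and got_controls >= n_controls:
                break
    causal_geno = np.vstack(rows)
    phenotype = np.asarray(pheno, dtype=np.int8)

    n_noise = n_snps - k
    lo, hi = noise_maf_range
    if not 0.0 < lo <= hi <= 0.5:
        raise ValueError("noise MAF range must satisfy 0 < lo <= hi <= 0.5")
    noise_mafs = rng.uniform(lo, hi, size=n_noise)
    noise_geno = _draw_hwe(rng, noise_mafs, n_total)

    positions = rng.permutation(n_snps)
    causal_pos = positions[:k]
    genotypes = np.empty((n_total, n_snps), dtype=np.int8)
    snp_ids = [""] * n_snps
    for j, pos in enumerate(causal_pos):
        genotypes[:, pos] = causal_geno[:, j]
        snp_ids[pos] = f"M{j}"
    for j, pos in enumerate(positions[k:]):
        genotypes[:, pos] = noise_geno[:, j]
        snp_ids[pos] = f"N{j}"

    dataset = GenotypeDataset(genotypes=genotypes, phenotype=phenotype, snp_ids=snp_ids)
    order_pos = np.sort(causal_pos)
    truth = SimulatedTruth(
        causal_snps=frozenset(int(p) for p in causal_pos),
        causal_ids=tuple(snp_ids[int(p)] for p in order_pos),
        order=k,
        model_class=model.model_class,
        heritability=model.heritability,
        prevalence=model.prevalence,
        seed=int(seed),
    )
    return dataset, truth


def write_truth_json(truth: SimulatedTruth, path) -> None:
    payload = {
        "causal_indices": sorted(truth.causal_snps),
        "causal_ids": list(truth.causal_ids),
        "order": truth.order,
        "model_class": truth.model_class,
        "heritability": truth.heritability,
        "prevalence": truth.prevalence,
        "seed": truth.seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth_json(path) -> SimulatedTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return SimulatedTruth(
        causal_snps=frozenset(int(i) for i in payload["causal_indices"]),
        causal_ids=tuple(payload["causal_ids"]),
        order=int(payload["order"]),
        model_class=payload["model_class"],
        heritability=float(payload["heritability"]),
        prevalence=float(payload["prevalence"]),
        seed=int(payload["seed"]),
    )
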