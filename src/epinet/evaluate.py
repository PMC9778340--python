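"""Power evaluation of detection results against simulated truth.

A solution (one reported module's member set) is scored by

    Acc = hit / order

where hit is the number of causal SNPs the solution contains and order is
the order of the planted interaction.  Non-causal members are not
penalised: the denominator is the truth order, not the solution size.
Over N replicates,

    Power_all  = (1/N) sum_i avg_j Acc(rel_ij)
    Power_best = (1/N) sum_i max_j Acc(rel_ij)

with a zero contribution from replicates that report no solutions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

from .simulate import SimulatedTruth

__all__ = ["PowerSummary", "acc", "power_summary", "write_power_json"]


@dataclass
class PowerSummary:
    """Per-replicate accuracies and the two power aggregates."""

    per_replicate_acc: list[list[float]]
    power_all: float
    power_best: float
    n_replicates: int


def acc(solution: Iterable, truth: SimulatedTruth) -> float:
    """Fraction of the planted causal SNPs present in one solution.

    Solution members may be SNP column indices or SNP identifier strings;
    both are matched against the truth.
    """
    members = set(solution)
    targets = set(truth.causal_snps) | set(truth.causal_ids)
    hit = len(members & targets)
    return hit / truth.order


def power_summary(
    results: Sequence[Sequence[Iterable]],
    truths: Sequence[SimulatedTruth],
) -> PowerSummary:
    """Aggregate Acc over replicates into Power_all and Power_best."""
    n = len(results)
    if n == 0:
        raise ValueError("need at least one replicate")
    if len(truths) != n:
        raise ValueError("results and truths must be aligned")
    per_rep: list[list[float]] = []
    total_avg = 0.0
    total_best = 0.0
    for solutions, truth in zip(results, truths):
        accs = [acc(s, truth) for s in solutions]
        per_rep.append(accs)
        if accs:
            total_avg += sum(accs) / len(accs)
            total_best += max(accs)
    return PowerSummary(
        per_replicate_acc=per_rep,
        power_all=total_avg / n,
        power_best=total_best / n,
        n_replicates=n,
    )


def write_power_json(summary: PowerSummary, path, meta: dict | None = None) -> None:
    payload = {
        "power_all": summary.power_all,
        "power_best": summary.power_best,
        "n_replicates": summary.n_replicates,
        "per_replicate_acc": summary.per_replicate_acc,
    }
    if meta:
        payload["meta"] = meta
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
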