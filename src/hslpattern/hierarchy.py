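"""Iterated population-based AND induction with n orthogonal signals.

An initial asymmetry splits a 1D population into two founder domains, each
producing a diffusible morphogen.  Population-based AND logic induces a new
domain wherever two signals coincide above threshold, and each new signal is
produced by the newest induced domain, spawning two further boundary domains
(AND with each signal flanking it).  With n orthogonal signaling systems the
scheme yields (2 x n) - 1 distinct domains.

The framework is qualitative, so the simulation runs in discrete synchronous
rounds with a shared 1D diffusion kernel and per-rule thresholds; labels are
permanent and earlier hierarchy levels win at contested positions.
"""
from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Rule", "HierarchyPlan", "DomainMap", "plan_hierarchy",
           "simulate_hierarchy", "count_domains"]


@dataclass(frozen=True)
class Rule:
    """signal-pair -> new domain, optionally producing a new signal."""

    inputs: tuple[str, str]
    domain: str
    produces: str | None
    level: int


@dataclass(frozen=True)
class HierarchyPlan:
    signals: tuple[str, ...]          # ordered morphogen names a, b, c, ...
    founders: tuple[str, str] | tuple[str]
    rules: tuple[Rule, ...]
    levels: dict = field(default_factory=dict)  # domain label -> level

    @property
    def domains(self) -> tuple[str, ...]:
        return tuple(self.levels.keys())

    @property
    def n_levels(self) -> int:
        return max(self.levels.values())


def _signal_names(n: int) -> list[str]:
    letters = string.ascii_lowercase
    return [letters[i] if i < 26 else f"s{i + 1}" for i in range(n)]


def plan_hierarchy(n: int) -> HierarchyPlan:
    """Plan the domain hierarchy for n orthogonal signals.

    n = 1 gives the single founder domain; n = 2 the two founders plus one
    boundary domain; each further signal is produced by the newest domain and
    spawns two new boundary domains (AND with each of its flanking signals).
    The planned domain count is 2n - 1.
    """
    if n < 1:
        raise ValueError("need at least one signaling system")
    sig = _signal_names(n)
    if n == 1:
        return HierarchyPlan(signals=(sig[0],), founders=("A",), rules=(),
                             levels={"A": 1})
    levels: dict[str, int] = {"A": 1, "B": 1}
    rules: list[Rule] = []
    # founders A and B produce the first two signals; their boundary domain
    # is induced by a AND b
    label0 = sig[0] + sig[1]
    produces0 = sig[2] if n >= 3 else None
    rules.append(Rule(inputs=(sig[0], sig[1]), domain=label0,
                      produces=produces0, level=2))
    levels[label0] = 2
    flanks = (sig[0], sig[1])  # signals flanking the newest domain
    for k in range(2, n):
        s_new = sig[k]
        level = k + 1
        next_producer_signal = sig[k + 1] if k + 1 < n else None
        new_flank_domains = []
        for side, s_flank in enumerate(flanks):
            label = "".join(sorted((s_flank, s_new)))
            # only the last-created domain of this level produces the next
            # signal (the newest-domain convention)
            produces = next_producer_signal if side == len(flanks) - 1 else None
            rules.append(Rule(inputs=(s_flank, s_new), domain=label,
                              produces=produces, level=level))
            levels[label] = level
            new_flank_domains.append((label, s_flank))
        # the newest domain sits between the new signal's source and its
        # second flank, so the next signal will flank s_new and that signal
        flanks = (s_new, new_flank_domains[-1][1])
    plan = HierarchyPlan(signals=tuple(sig), founders=("A", "B"),
                         rules=tuple(rules), levels=levels)
    assert len(plan.domains) == 2 * n - 1
    return plan


@dataclass
class DomainMap:
    """Lattice of positions -> domain label (or None) plus signal fields."""

    labels: np.ndarray                # object array of labels / None
    fields: dict[str, np.ndarray]
    plan: HierarchyPlan
    incomplete: bool = False

    def intervals(self) -> dict[str, list[tuple[int, int]]]:
        """Maximal contiguous intervals (0-based, inclusive) per label."""
        out: dict[str, list[tuple[int, int]]] = {}
        lab = self.labels
        i = 0
        while i < len(lab):
            if lab[i] is None:
                i += 1
                continue
            j = i
            while j + 1 < len(lab) and lab[j + 1] == lab[i]:
                j += 1
            out.setdefault(lab[i], []).append((i, j))
            i = j + 1
        return out


def count_domains(domain_map: DomainMap) -> int:
    """Number of distinct domain labels present on the lattice."""
    return len({l for l in domain_map.labels.tolist() if l is not None})


def _blur(f: np.ndarray, passes: int) -> np.ndarray:
    """Shared diffusion kernel: iterated 3-cell box blur, reflecting ends."""
    for _ in range(passes):
        padded = np.concatenate((f[:1], f, f[-1:]))
        f = (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0
    return f


def simulate_hierarchy(plan: HierarchyPlan, length: int = 64,
                       rounds: int = 16, production: float = 1.0,
                       retention: float = 0.8, blur_passes: int = 3,
                       threshold: float = 0.8,
                       threshold_decay: float = 0.7,
                       settle: int = 4) -> DomainMap:
    """Run the discrete-round induction dynamics for a plan.

    Each round, every signal with an existing producer domain is replenished
    (production per producing cell), partially retained (1 - decay), and
    diffused with the shared kernel; then the rules fire in hierarchy order,
    claiming founder-labeled (or unlabeled) cells where both input signals
    exceed the threshold.  Induced labels are permanent and earlier levels
    win contested cells; founder domains are the overwritable background.

    rounds must reach at least n_levels - 1 for the full hierarchy to be able
    to resolve; shallower runs return incomplete = True.
    """
    if length < 4:
        raise ValueError("lattice too short")
    labels = np.array([None] * length, dtype=object)
    half = length // 2
    if len(plan.founders) == 1:
        labels[:] = plan.founders[0]
    else:
        labels[:half] = plan.founders[0]
        labels[half:] = plan.founders[1]
    fields = {s: np.zeros(length) for s in plan.signals}
    producer: dict[str, str] = {}
    if len(plan.signals) >= 1:
        producer[plan.signals[0]] = plan.founders[0]
    if len(plan.signals) >= 2 and len(plan.founders) > 1:
        producer[plan.signals[1]] = plan.founders[1]
    for rule in plan.rules:
        if rule.produces:
            producer[rule.produces] = rule.domain

    rules = sorted(plan.rules, key=lambda r: r.level)
    for _ in range(max(rounds, 0)):
        # morphogen release and transport equilibrate faster than domain
        # induction, so fields settle over several sub-rounds per round
        for _sub in range(max(settle, 1)):
            for s in plan.signals:
                src = producer.get(s)
                if src is None:
                    continue
                mask = (labels == src)
                fields[s] = _blur(retention * fields[s] + production * mask,
                                  blur_passes)
        for level in sorted({r.level for r in rules}):
            # founder labels are the overwritable background state; induced
            # labels are permanent, so earlier levels win contested cells.
            claimable = np.array([l is None or l in plan.founders
                                  for l in labels])
            # cells contested by rules of the same level are resolved by
            # specificity first (the pair whose least-derived input is more
            # derived wins: its region is nested inside the other's), then by
            # induction strength (product of the two input signals); exact
            # ties break toward the earlier-listed rule
            # generation: both founder morphogens are 0, each later signal
            # one more than the previous
            gen = {s: max(i - 1, 0) for i, s in enumerate(plan.signals)}
            spec = np.full(length, -1)
            strength = np.full(length, -np.inf)
            winner = np.full(length, -1)
            for ri, rule in enumerate(r for r in rules if r.level == level):
                th = threshold * threshold_decay ** (rule.level - 2)
                sa, sb = fields[rule.inputs[0]], fields[rule.inputs[1]]
                rule_spec = min(gen[rule.inputs[0]], gen[rule.inputs[1]])
                ok = (sa > th) & (sb > th) & claimable
                take = ok & ((rule_spec > spec) |
                             ((rule_spec == spec) & (sa * sb > strength)))
                spec[take] = rule_spec
                strength[take] = (sa * sb)[take]
                winner[take] = ri
            level_rules = [r for r in rules if r.level == level]
            for ri, rule in enumerate(level_rules):
                labels[winner == ri] = rule.domain
    incomplete = rounds < plan.n_levels - 1 or \
        count_domains(DomainMap(labels, fields, plan)) < len(plan.domains)
    return DomainMap(labels=labels, fields=fields, plan=plan,
                     incomplete=incomplete)
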