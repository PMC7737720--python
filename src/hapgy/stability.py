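"""Stability classification of haplotype-block associations.

An association is *environment-specific stable* when, within one testing
environment, some trial (EYT cohort) reaches p < 1e-4 and at least three
trials reach p < 1e-3 (the strong trial counts toward the three).  It is
*multi-environment stable* when p < 1e-3 hits span at least two distinct
environments and at least two distinct trials jointly.  A block may carry
both labels.  No multiple-testing correction is applied beyond these fixed
thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from hapgy.assoc import AssocResult


@dataclass
class StabilityCriteria:
    p_strong: float = 1e-4
    p_weak: float = 1e-3
    min_eyts_env: int = 3
    min_envs: int = 2
    min_eyts_multi: int = 2

    def __post_init__(self):
        if self.p_strong > self.p_weak:
            raise ValueError("p_strong must be <= p_weak")


@dataclass
class StableAssociation:
    block_id: str
    category: str  # "env_specific:<ENV>" or "multi_env"
    supporting: list = field(default_factory=list)  # (trial_id, environment, p) tuples
    favorable_alleles: list = field(default_factory=list)


def _group_by_block(results, env=None):
    by_block = {}
    for r in results:
        if env is not None and r.environment != env:
            continue
        by_block.setdefault(r.block_id, []).append(r)
    return by_block


def env_stable(results, env: str, criteria: StabilityCriteria = None) -> list:
    """Blocks stable for one testing environment across trials."""
    c = criteria or StabilityCriteria()
    out = []
    for block_id, rs in sorted(_group_by_block(results, env=env).items()):
        weak_trials = {r.trial_id for r in rs if r.p_value < c.p_weak}
        has_strong = any(r.p_value < c.p_strong for r in rs)
        if has_strong and len(weak_trials) >= c.min_eyts_env:
            support = sorted(
                [(r.trial_id, r.environment, r.p_value) for r in rs if r.p_value < c.p_weak]
            )
            fav = _favorable_union(rs, c.p_weak)
            out.append(
                StableAssociation(
                    block_id=block_id,
                    category=f"env_specific:{env}",
                    supporting=support,
                    favorable_alleles=fav,
                )
            )
    return out


def multienv_stable(results, criteria: StabilityCriteria = None) -> list:
    """Blocks whose sub-threshold hits span >= 2 environments and >= 2 trials."""
    c = criteria or StabilityCriteria()
    out = []
    for block_id, rs in sorted(_group_by_block(results).items()):
        hits = [r for r in rs if r.p_value < c.p_weak]
        envs = {r.environment for r in hits}
        trials = {r.trial_id for r in hits}
        if len(envs) >= c.min_envs and len(trials) >= c.min_eyts_multi:
            support = sorted((r.trial_id, r.environment, r.p_value) for r in hits)
            out.append(
                StableAssociation(
                    block_id=block_id,
                    category="multi_env",
                    supporting=support,
                    favorable_alleles=_favorable_union(rs, c.p_weak),
                )
            )
    return out


def _favorable_union(rs, p_weak):
    """Favorable alleles pooled over the qualifying hits, majority first."""
    votes = {}
    for r in rs:
        if r.p_value < p_weak:
            for a in r.favorable_alleles:
                votes[a] = votes.get(a, 0) + 1
    return [a for a, _ in sorted(votes.items(), key=lambda kv: (-kv[1], str(kv[0])))]
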