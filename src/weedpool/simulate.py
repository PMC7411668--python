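"""Synthetic plot-survey and taxon-table generation with known truth.

The generator emulates, at desk scale, plot-based vegetation surveys over a
landscape of discrete habitats. Each species has a *home habitat* and a
specialization s in [0, 1]: it occurs in a plot of its home habitat with
probability ``p_occ`` and in plots of any other habitat with probability
``p_occ * (1 - s)``, independently across plots. s = 1 gives a strict
specialist, s = 0 a perfect generalist with a flat habitat profile.
Because the model is fully known, the participation coefficient each
species should converge to is available in closed form (``expected_c``),
which is what makes planted-truth recovery testable end to end.

Taxon attribute tables (life form, origin, red-list status, source
memberships) are drawn independently per taxon from configurable marginal
proportions; defaults reflect the composition typical of the French arable
weed flora (therophyte-dominated, strong Mediterranean element).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .network import IncidenceMatrix
from .pool import SpeciesPool, TaxonRecord

DEFAULT_ATTRIBUTE_MARGINALS: dict[str, dict[str, float]] = {
    "life_form": {
        "therophyte": 0.604,
        "hemicryptophyte": 0.257,
        "geophyte": 0.096,
        "chamaephyte": 0.008,
        "phanerophyte": 0.009,
        "other": 0.026,
    },
    "origin": {
        "mediterranean": 602 / 1514,
        "european": 284 / 1514,
        "eurasian": 251 / 1514,
        "cosmopolitan": 121 / 1514,
        "introduced": 105 / 1514,
        "other": 151 / 1514,
    },
    "red_list": {"listed": 98 / 1514, "not_listed": 1416 / 1514},
}

DEFAULT_MEMBERSHIP_PROBS: dict[str, float] = {
    "flora": 1402 / 1514,
    "segetal_list": 258 / 1514,
    "national_survey": 332 / 1514,
    "regional_survey": 399 / 1514,
}


@dataclass
class SyntheticConfig:
    """Study-condition parameters for the survey generator.

    ``s`` may be a scalar (every species equally specialized) or a
    (low, high) range sampled uniformly per species. ``weed_s`` /
    ``non_weed_s``, when given, override ``s`` for species flagged as weeds
    / non-weeds, planting a generalism contrast between the groups.
    """

    H: int = 4            # habitats
    P: int = 100          # plots per habitat
    S: int = 50           # species per habitat pool
    s: float | tuple[float, float] = (0.0, 1.0)
    p_occ: float = 0.5    # occurrence probability in home-habitat plots
    weed_fraction: float = 0.5
    weed_s: float | tuple[float, float] | None = None
    non_weed_s: float | tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.H < 2:
            raise ValueError("need at least 2 habitats")
        if self.P < 1 or self.S < 1:
            raise ValueError("P and S must be >= 1")
        if not 0 <= self.p_occ <= 1:
            raise ValueError("p_occ must be in [0, 1]")
        if not 0 <= self.weed_fraction <= 1:
            raise ValueError("weed_fraction must be in [0, 1]")
        for v in (self.s, self.weed_s, self.non_weed_s):
            if v is None:
                continue
            lo, hi = (v, v) if np.isscalar(v) else v
            if not (0 <= lo <= hi <= 1):
                raise ValueError(f"specialization out of [0, 1]: {v!r}")


@dataclass
class SyntheticTruth:
    """Planted parameters of one simulated survey."""

    home_habitat: dict[str, str]
    specialization: dict[str, float]
    expected_c: dict[str, float]
    is_weed: dict[str, bool]
    plot_habitat: dict[str, str]


def expected_c(s: float, p_occ: float, H: int, P: int) -> float:
    """Closed-form participation coefficient implied by the model.

    Uses the expected occurrence counts e_home = P*p_occ and
    e_away = P*p_occ*(1-s) per away habitat:
    c* = 1 - (e_home^2 + (H-1) e_away^2) / (e_home + (H-1) e_away)^2.
    """
    if not (0 <= s <= 1 and 0 < p_occ <= 1 and H >= 2 and P >= 1):
        raise ValueError("invalid parameters")
    e_home = P * p_occ
    e_away = P * p_occ * (1.0 - s)
    total = e_home + (H - 1) * e_away
    if total == 0:
        raise ValueError("all expected occupancies are zero")
    return float(1.0 - (e_home**2 + (H - 1) * e_away**2) / total**2)


def _draw_s(spec: float | tuple[float, float], size: int,
            rng: np.random.Generator) -> np.ndarray:
    if np.isscalar(spec):
        return np.full(size, float(spec))
    lo, hi = spec
    return rng.uniform(lo, hi, size)


def simulate_survey(config: SyntheticConfig) -> tuple[IncidenceMatrix, SyntheticTruth]:
    """Sample one plot survey; returns the incidence and the planted truth.

    Species observed nowhere are dropped from the incidence matrix but kept
    in the truth tables. Bit-identical output for equal configs.
    """
    rng = np.random.default_rng(config.seed)
    H, P, S = config.H, config.P, config.S
    n_sp = H * S
    species = [f"sp{i:04d}" for i in range(n_sp)]
    home = np.repeat(np.arange(H), S)
    weed = rng.random(n_sp) < config.weed_fraction
    s_i = _draw_s(config.s, n_sp, rng)
    if config.weed_s is not None:
        s_i[weed] = _draw_s(config.weed_s, int(weed.sum()), rng)
    if config.non_weed_s is not None:
        s_i[~weed] = _draw_s(config.non_weed_s, int((~weed).sum()), rng)

    plots = [f"h{h + 1}_p{k:03d}" for h in range(H) for k in range(P)]
    plot_hab = np.repeat(np.arange(H), P)
    # occurrence probability matrix: home plots p_occ, away p_occ*(1-s)
    at_home = plot_hab[:, None] == home[None, :]
    prob = np.where(at_home, config.p_occ, config.p_occ * (1.0 - s_i)[None, :])
    presence = rng.random((H * P, n_sp)) < prob

    truth = SyntheticTruth(
        home_habitat={sp: str(h + 1) for sp, h in zip(species, home)},
        specialization={sp: float(v) for sp, v in zip(species, s_i)},
        expected_c={
            sp: expected_c(float(v), config.p_occ, H, P)
            for sp, v in zip(species, s_i)
        },
        is_weed={sp: bool(w) for sp, w in zip(species, weed)},
        plot_habitat={pl: str(h + 1) for pl, h in zip(plots, plot_hab)},
    )
    observed = presence.any(axis=0)
    inc = IncidenceMatrix(
        plots=plots,
        species=[sp for sp, k in zip(species, observed) if k],
        presence=presence[:, observed],
    )
    return inc, truth


def simulate_pool(
    n_taxa: int,
    attribute_marginals: Mapping[str, Mapping[str, float]] | None = None,
    membership_probs: Mapping[str, float] | None = None,
    seed: int = 0,
) -> SpeciesPool:
    """Draw a taxon attribute table with independent categorical marginals.

    Marginals must sum to 1 per attribute (tolerance 1e-9); source
    memberships are independent Bernoulli draws per source.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    marginals = dict(attribute_marginals or DEFAULT_ATTRIBUTE_MARGINALS)
    probs = dict(membership_probs or DEFAULT_MEMBERSHIP_PROBS)
    for attr, dist in marginals.items():
        total = sum(dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"marginals for {attr!r} sum to {total}, not 1")
    for src, p in probs.items():
        if not 0 <= p <= 1:
            raise ValueError(f"membership probability for {src!r} out of [0, 1]")

    rng = np.random.default_rng(seed)
    taxa = []
    sources = list(probs)
    for i in range(n_taxa):
        attrs = {}
        for attr, dist in marginals.items():
            cats = list(dist)
            attrs[attr] = str(rng.choice(cats, p=[dist[c] for c in cats]))
        member = {s for s in sources if rng.random() < probs[s]}
        name = f"Genus{i // 26:03d} species{i:04d}"
        taxa.append(TaxonRecord(taxon_id=name, name=name,
                                memberships=member, **attrs))
    return SpeciesPool(taxa=taxa, sources=sources)
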