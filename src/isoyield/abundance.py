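"""Tandem qPCR x amplicon arithmetic for whole-community guild abundances.

qPCR with domain-general primers gives absolute 16S copy numbers per gram of
biomass for Bacteria and Archaea; amplicon sequencing gives each guild's
relative abundance *within* its domain.  Multiplying the domain's share of
total copies by the within-domain guild fraction places every guild on a
common whole-community percentage scale — e.g. ammonia-oxidizing archaea that
make up 0.45 % of archaeal reads can still be negligible community-wide when
archaea contribute only ~0.02 % of all 16S copies.

Uncertainty on the shares is propagated to first order (delta method) from
the stated copy-number standard deviations; this is approximate and ignores
amplicon-fraction uncertainty unless provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

from .errors import GuildLookupError, UndefinedShareError

Domain = Literal["bacteria", "archaea"]


@dataclass
class CommunityQuant:
    """Domain copy numbers (copies/g VSS) and within-domain guild fractions."""

    bacterial_copies: float
    archaeal_copies: float
    guild_fraction_within_domain: dict[tuple[str, Domain], float] = field(
        default_factory=dict
    )
    bacterial_copies_sd: float = 0.0
    archaeal_copies_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.bacterial_copies < 0 or self.archaeal_copies < 0:
            raise ValueError("copy numbers must be >= 0")
        for key, frac in self.guild_fraction_within_domain.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"guild fraction for {key} must be in [0, 1]")

    def copies(self, domain: Domain) -> float:
        return self.bacterial_copies if domain == "bacteria" else self.archaeal_copies


@dataclass
class Share:
    """A percentage of the total community with first-order uncertainty."""

    percent: float
    sd: float  # delta-method, approximate


def domain_share(quant: CommunityQuant, domain: Domain) -> Share:
    """Domain's percentage of all 16S copies (bacterial + archaeal)."""
    total = quant.bacterial_copies + quant.archaeal_copies
    if total <= 0:
        raise UndefinedShareError("zero total copy number")
    own = quant.copies(domain)
    other = total - own
    pct = 100.0 * own / total
    # d(pct)/d(own) = 100*other/total^2, d(pct)/d(other) = -100*own/total^2
    sd_own = (
        quant.bacterial_copies_sd if domain == "bacteria" else quant.archaeal_copies_sd
    )
    sd_other = (
        quant.archaeal_copies_sd if domain == "bacteria" else quant.bacterial_copies_sd
    )
    sd = (
        100.0
        / total**2
        * math.hypot(other * sd_own, own * sd_other)
    )
    return Share(percent=pct, sd=sd)


def guild_total_abundance(
    quant: CommunityQuant,
    guild: str,
    domain: Domain,
    *,
    guild_fraction_sd: float = 0.0,
) -> Share:
    """Guild's percentage of the whole community.

    ``domain_share/100 * guild_fraction_within_domain * 100``; the guild can
    never exceed its domain's share.
    """
    key = (guild, domain)
    if key not in quant.guild_fraction_within_domain:
        raise GuildLookupError(f"no guild fraction recorded for {key}")
    frac = quant.guild_fraction_within_domain[key]
    dom = domain_share(quant, domain)
    pct = dom.percent * frac
    sd = math.hypot(frac * dom.sd, dom.percent * guild_fraction_sd)
    return Share(percent=pct, sd=sd)
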