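"""Stochastic partition: gene switching, DSB and TNF-receptor event channels.

Each of the two alleles of a switched gene is either active or inactive, so
the gene state is 0, 1 or 2 active copies.  Activation propensity is
proportional to the levels of the gene's transcription-factor activators
(optionally damped by an inhibitor through a factor K/(K+inhibitor)) and to
the number of inactive alleles; deactivation is spontaneous and
regulator-independent.  DSB appearance/repair and TNF receptor
activation/deactivation are the other two event classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ContractViolation(ValueError):
    pass


@dataclass(frozen=True)
class GeneDef:
    """A stochastically switched gene with two alleles.

    ``regulators`` is a tuple of ``(activator_species, weight_param,
    inhibitor_species_or_None, inhibition_K_param_or_None)``.  The
    activation propensity is::

        (q0 + sum_i q_i * level_i * [K_i / (K_i + inhibitor_i)]) * (copies - g)

    and the deactivation propensity is ``d * g``.
    """

    name: str
    basal: str                      # parameter name for q0
    deactivation_rate: str          # parameter name for d
    regulators: tuple = ()
    copies: int = 2

    def param_names(self):
        names = [self.basal, self.deactivation_rate]
        for _, q, _, K in self.regulators:
            names.append(q)
            if K is not None:
                names.append(K)
        return names

    def to_dict(self):
        return {
            "name": self.name,
            "basal": self.basal,
            "deactivation_rate": self.deactivation_rate,
            "regulators": [list(r) for r in self.regulators],
            "copies": self.copies,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            name=d["name"], basal=d["basal"],
            deactivation_rate=d["deactivation_rate"],
            regulators=tuple(tuple(r) for r in d["regulators"]),
            copies=d.get("copies", 2),
        )


@dataclass
class EventChannel:
    """A stochastic event channel: a propensity and a discrete state update.

    ``propensity(state)`` returns a rate in 1/s; ``effect`` is a dict of
    discrete updates, e.g. ``{"gene": ("wip1", +1)}``, ``{"dsb": +1}`` or
    ``{"receptors": -1}``.
    """

    name: str
    propensity: callable
    effect: dict = field(default_factory=dict)

    def apply(self, state):
        if "gene" in self.effect:
            gname, dg = self.effect["gene"]
            new = state.genes[gname] + dg
            if not 0 <= new <= 2:
                raise ContractViolation(
                    f"gene {gname!r} driven outside {{0,1,2}}")
            state.genes[gname] = new
        if "dsb" in self.effect:
            new = state.dsb + self.effect["dsb"]
            if new < 0:
                raise ContractViolation("DSB count driven below 0")
            state.dsb = new
        if "receptors" in self.effect:
            new = state.receptors_active + self.effect["receptors"]
            if new < 0:
                raise ContractViolation("receptor count driven below 0")
            state.receptors_active = new


# ---------------------------------------------------------------------------
# propensity functions (reference path; the numba kernel mirrors these)
# ---------------------------------------------------------------------------

def gene_activation_propensity(gene: GeneDef, state, spec) -> float:
    """Activation rate (1/s): regulator-weighted, scaled by inactive alleles."""
    g = state.genes[gene.name]
    inactive = gene.copies - g
    if inactive <= 0:
        return 0.0
    pars = spec.parameters
    a = pars[gene.basal]
    for sp, q, inh, K in gene.regulators:
        level = state.y[spec.index[sp]]
        if level < 0:
            raise ContractViolation(f"negative regulator level for {sp!r}")
        term = pars[q] * level
        if inh is not None:
            Kv = pars[K]
            term *= Kv / (Kv + state.y[spec.index[inh]])
        a += term
    return a * inactive


def gene_deactivation_propensity(gene: GeneDef, state, spec) -> float:
    """Spontaneous deactivation: rate = d * active alleles."""
    return spec.parameters[gene.deactivation_rate] * state.genes[gene.name]


def dsb_channels(dose_rate_gy_s: float, state, spec):
    """(induction, repair) propensities for the DSB birth/death channel.

    Induction: ``dsb_per_gy * dose_rate + background``; repair is
    repair-complex limited: ``vmax * dsb / (km + dsb)``.
    """
    if dose_rate_gy_s < 0:
        raise ContractViolation("negative dose rate")
    p = spec.parameters
    ch = spec.dsb_channel
    induction = p[ch.k_per_gy] * dose_rate_gy_s + p[ch.k_background]
    repair = p[ch.vmax_repair] * state.dsb / (p[ch.km_repair] + state.dsb)
    return induction, repair


def tnf_receptor_channels(tnf_level: float, state, spec):
    """(activation, deactivation) propensities for the TNF receptor pool."""
    if tnf_level < 0:
        raise ContractViolation("negative TNF level")
    p = spec.parameters
    rc = spec.receptor_channel
    inactive = p[rc.pool] - state.receptors_active
    act = p[rc.k_on] * tnf_level * max(inactive, 0.0)
    deact = p[rc.k_off] * state.receptors_active
    return act, deact


def build_channels(spec, dose_rate_fn, tnf_fn):
    """All event channels of a spec, with time-dependent protocol inputs."""
    channels = []
    for gene in spec.genes:
        channels.append(EventChannel(
            f"{gene.name}_on",
            lambda s, g=gene: gene_activation_propensity(g, s, spec),
            {"gene": (gene.name, +1)}))
        channels.append(EventChannel(
            f"{gene.name}_off",
            lambda s, g=gene: gene_deactivation_propensity(g, s, spec),
            {"gene": (gene.name, -1)}))
    channels.append(EventChannel(
        "dsb_induction",
        lambda s: dsb_channels(dose_rate_fn(s.t), s, spec)[0],
        {"dsb": +1}))
    channels.append(EventChannel(
        "dsb_repair",
        lambda s: dsb_channels(dose_rate_fn(s.t), s, spec)[1],
        {"dsb": -1}))
    channels.append(EventChannel(
        "receptor_on",
        lambda s: tnf_receptor_channels(tnf_fn(s.t), s, spec)[0],
        {"receptors": +1}))
    channels.append(EventChannel(
        "receptor_off",
        lambda s: tnf_receptor_channels(tnf_fn(s.t), s, spec)[1],
        {"receptors": -1}))
    return channels
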