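"""Deterministic reaction network of the ATM/p53/NF-kB/Wip1 DNA damage response.

The model describes a single mammalian cell (parameterised for the U2-OS
osteosarcoma line) in three well-mixed compartments -- extracellular matrix,
cytoplasm and nucleus.  Double-strand breaks (DSBs) are detected by the
MRN complex and ATM kinase; active ATM drives p53 (via direct
phosphorylation and via Chk2), destabilises Mdm2, and activates the
NF-kB module through IKK.  The Wip1 phosphatase is the switch-off element:
it is transcriptionally induced by p53, CREB and NF-kB, post-transcriptionally
repressed by miR-16 (whose biogenesis is promoted by ATM-activated KSRP),
and dephosphorylates ATM, Chk2, p53 and multi-phosphorylated Mdm2.
p21 and Bax are the arrest and apoptosis readouts.

Levels are molecule counts per cell, time is in seconds.  The network is
*data driven*: every ordinary-differential-equation term is a row in a
declarative reaction table (:class:`Reaction`), so each transcription,
(de)phosphorylation, transport or degradation step can be inspected and
unit-tested in isolation.  The same table is compiled to a packed array
form consumed by the numba simulation kernel (:mod:`ddrsim.engine`).

Rate-law conventions: mass action for synthesis, degradation, binding and
transport; Michaelis-Menten for enzymatic (de)phosphorylation (ATM, Chk2,
Wip1, MRN actions); transcription proportional to active allele count for
the stochastically switched genes.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .genes import GeneDef

COMPARTMENTS = ("extracellular", "cytoplasm", "nucleus")
FORMS = ("protein", "protein_phospho", "protein_multiphospho", "mRNA", "miRNA",
         "complex")
PARTITIONS = ("deterministic", "stochastic")

#: reaction kinds understood by the evaluator / kernel
KINDS = (
    "const",    # k                          (constitutive source)
    "lin",      # k * y[s1]                  (1st order: decay, conversion, transport)
    "bilin",    # k * y[s1] * y[s2]          (mass-action binding / enzymatic)
    "mm",       # k * y[s1] * y[s2]/(K+y[s2])   s1 = enzyme, s2 = substrate
    "lininh",   # k * y[s1] * K/(K + y[s2])  (transcription with repressor)
    "gene",     # k * g[gene]                (transcription from active alleles)
    "dsblin",   # k * dsb * y[s1]            (damage-driven activation)
    "reclin",   # k * rec * y[s1]            (TNF-receptor-driven activation)
    "sat",      # k * y[s1]/(K + y[s1])      (fixed-capacity enzymatic removal)
)


class ModelLoadError(ValueError):
    """Raised when a model definition references an undeclared symbol."""


@dataclass(frozen=True)
class Species:
    """One molecular species in one compartment."""

    name: str
    compartment: str
    form: str = "protein"
    partition: str = "deterministic"

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ModelLoadError(
                f"species {self.name!r}: unknown compartment {self.compartment!r}")
        if self.form not in FORMS:
            raise ModelLoadError(f"species {self.name!r}: unknown form {self.form!r}")
        if self.partition not in PARTITIONS:
            raise ModelLoadError(
                f"species {self.name!r}: unknown partition {self.partition!r}")


@dataclass(frozen=True)
class Reaction:
    """One rate-law term contributing to one or more species derivatives.

    ``stoich`` maps species name -> signed stoichiometric coefficient.
    ``transport`` marks cross-compartment shuttling terms, which must
    appear with opposite signs in source and destination compartments.
    """

    name: str
    kind: str
    k: str                      # rate-constant parameter name
    s1: str | None = None
    s2: str | None = None
    K: str | None = None        # Michaelis / inhibition constant parameter
    gene: str | None = None
    stoich: tuple = ()          # tuple of (species, coef)
    transport: bool = False

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ModelLoadError(f"reaction {self.name!r}: unknown kind {self.kind!r}")


@dataclass
class DsbChannel:
    """Stochastic DSB appearance/repair event channel definition.

    Induction propensity: ``k_per_gy * dose_rate + k_background``.
    Repair propensity (repair-complex limited): ``vmax * dsb / (km + dsb)``.
    """

    k_per_gy: str = "dsb_per_gy"
    k_background: str = "k_dsb_bg"
    vmax_repair: str = "vmax_repair"
    km_repair: str = "km_repair"


@dataclass
class ReceptorChannel:
    """TNF receptor activation/deactivation event channel definition."""

    pool: str = "n_receptors"
    k_on: str = "k_rec_on"      # per receptor per (ng/ml) per s
    k_off: str = "k_rec_off"    # per active receptor per s


@dataclass
class CellState:
    """Full dynamic state of one cell."""

    t: float
    y: np.ndarray                      # continuous species levels (molecules)
    genes: dict                        # gene name -> active allele count {0,1,2}
    dsb: int = 0
    receptors_active: int = 0

    def validate(self):
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite species level")
        if np.any(self.y < 0):
            bad = int(np.argmin(self.y))
            raise ValueError(f"negative species level at index {bad}")
        for g, v in self.genes.items():
            if v not in (0, 1, 2):
                raise ValueError(f"gene {g!r} allele count {v} outside {{0,1,2}}")
        if self.dsb < 0 or self.receptors_active < 0:
            raise ValueError("negative discrete count")


class ModelSpec:
    """Species inventory, parameter table, reaction table and event channels."""

    def __init__(self, species, parameters, reactions, genes,
                 dsb_channel=None, receptor_channel=None,
                 param_kinds=None, fitted=(), input_species=("tnf_e",)):
        self.species = list(species)
        self.parameters = dict(parameters)
        self.reactions = list(reactions)
        self.genes = list(genes)
        self.dsb_channel = dsb_channel or DsbChannel()
        self.receptor_channel = receptor_channel or ReceptorChannel()
        self.param_kinds = dict(param_kinds or {})
        self.fitted = tuple(fitted)
        self.input_species = tuple(input_species)
        self.index = {s.name: i for i, s in enumerate(self.species)}
        self.gene_index = {g.name: i for i, g in enumerate(self.genes)}
        self._resting = None
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self):
        if len(self.index) != len(self.species):
            raise ModelLoadError("duplicate species name")
        for p, v in self.parameters.items():
            if self.param_kinds.get(p, "rate") in ("rate", "count", "K") and v < 0:
                raise ModelLoadError(f"parameter {p!r} is negative")
        for r in self.reactions:
            for pname in (r.k, r.K):
                if pname is not None and pname not in self.parameters:
                    raise ModelLoadError(
                        f"reaction {r.name!r}: undeclared parameter {pname!r}")
            for sname in (r.s1, r.s2):
                if sname is not None and sname not in self.index:
                    raise ModelLoadError(
                        f"reaction {r.name!r}: undeclared species {sname!r}")
            if r.gene is not None and r.gene not in self.gene_index:
                raise ModelLoadError(
                    f"reaction {r.name!r}: undeclared gene {r.gene!r}")
            if r.kind == "gene" and r.gene is None:
                raise ModelLoadError(f"reaction {r.name!r}: gene kind needs a gene")
            for sname, _ in r.stoich:
                if sname not in self.index:
                    raise ModelLoadError(
                        f"reaction {r.name!r}: stoichiometry on undeclared "
                        f"species {sname!r}")
        for g in self.genes:
            for sp, _, inh, _K in g.regulators:
                if sp not in self.index:
                    raise ModelLoadError(
                        f"gene {g.name!r}: undeclared activator {sp!r}")
                if inh is not None and inh not in self.index:
                    raise ModelLoadError(
                        f"gene {g.name!r}: undeclared inhibitor {inh!r}")
            for pname in g.param_names():
                if pname not in self.parameters:
                    raise ModelLoadError(
                        f"gene {g.name!r}: undeclared parameter {pname!r}")
        ch = self.dsb_channel
        for pname in (ch.k_per_gy, ch.k_background, ch.vmax_repair, ch.km_repair):
            if pname not in self.parameters:
                raise ModelLoadError(f"DSB channel: undeclared parameter {pname!r}")
        rc = self.receptor_channel
        for pname in (rc.pool, rc.k_on, rc.k_off):
            if pname not in self.parameters:
                raise ModelLoadError(
                    f"receptor channel: undeclared parameter {pname!r}")

    # -- introspection ------------------------------------------------------
    @property
    def n_species(self):
        return len(self.species)

    @property
    def n_genes(self):
        return len(self.genes)

    def compartments_of(self, base):
        """Species names whose name starts with ``base + '_'``."""
        return [s.name for s in self.species if s.name.split("_")[0] == base]

    def copy(self):
        c = copy.deepcopy(self)
        c._resting = None
        return c

    def spec_hash(self):
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    # -- serialization ------------------------------------------------------
    def to_dict(self):
        return {
            "species": [asdict(s) for s in self.species],
            "parameters": {k: float(v) for k, v in self.parameters.items()},
            "param_kinds": dict(self.param_kinds),
            "fitted": list(self.fitted),
            "input_species": list(self.input_species),
            "reactions": [
                {**asdict(r), "stoich": [list(x) for x in r.stoich]}
                for r in self.reactions
            ],
            "genes": [g.to_dict() for g in self.genes],
            "dsb_channel": asdict(self.dsb_channel),
            "receptor_channel": asdict(self.receptor_channel),
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            species=[Species(**s) for s in d["species"]],
            parameters=d["parameters"],
            reactions=[
                Reaction(**{**r, "stoich": tuple(tuple(x) for x in r["stoich"])})
                for r in d["reactions"]
            ],
            genes=[GeneDef.from_dict(g) for g in d["genes"]],
            dsb_channel=DsbChannel(**d["dsb_channel"]),
            receptor_channel=ReceptorChannel(**d["receptor_channel"]),
            param_kinds=d.get("param_kinds"),
            fitted=d.get("fitted", ()),
            input_species=d.get("input_species", ("tnf_e",)),
        )

    def to_yaml(self, path):
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    # -- packed representation for the kernel -------------------------------
    def pack(self):
        """Compile the reaction/gene tables into flat numpy arrays."""
        kind_code = {k: i for i, k in enumerate(KINDS)}
        n = len(self.reactions)
        max_tgt = max((len(r.stoich) for r in self.reactions), default=1)
        P = {
            "ttype": np.zeros(n, dtype=np.int64),
            "kval": np.zeros(n),
            "Kval": np.zeros(n),
            "s1": np.full(n, -1, dtype=np.int64),
            "s2": np.full(n, -1, dtype=np.int64),
            "gidx": np.full(n, -1, dtype=np.int64),
            "ntgt": np.zeros(n, dtype=np.int64),
            "tgt": np.full((n, max_tgt), -1, dtype=np.int64),
            "coef": np.zeros((n, max_tgt)),
        }
        for i, r in enumerate(self.reactions):
            P["ttype"][i] = kind_code[r.kind]
            P["kval"][i] = self.parameters[r.k]
            P["Kval"][i] = self.parameters[r.K] if r.K else 1.0
            if r.s1 is not None:
                P["s1"][i] = self.index[r.s1]
            if r.s2 is not None:
                P["s2"][i] = self.index[r.s2]
            if r.gene is not None:
                P["gidx"][i] = self.gene_index[r.gene]
            P["ntgt"][i] = len(r.stoich)
            for j, (sname, c) in enumerate(r.stoich):
                P["tgt"][i, j] = self.index[sname]
                P["coef"][i, j] = c

        ng = len(self.genes)
        max_reg = max((len(g.regulators) for g in self.genes), default=1)
        G = {
            "q0": np.zeros(ng),
            "d": np.zeros(ng),
            "copies": np.zeros(ng, dtype=np.int64),
            "nreg": np.zeros(ng, dtype=np.int64),
            "reg_sp": np.full((ng, max_reg), -1, dtype=np.int64),
            "reg_q": np.zeros((ng, max_reg)),
            "reg_inh": np.full((ng, max_reg), -1, dtype=np.int64),
            "reg_K": np.ones((ng, max_reg)),
        }
        for i, g in enumerate(self.genes):
            G["q0"][i] = self.parameters[g.basal]
            G["d"][i] = self.parameters[g.deactivation_rate]
            G["copies"][i] = g.copies
            G["nreg"][i] = len(g.regulators)
            for j, (sp, q, inh, K) in enumerate(g.regulators):
                G["reg_sp"][i, j] = self.index[sp]
                G["reg_q"][i, j] = self.parameters[q]
                if inh is not None:
                    G["reg_inh"][i, j] = self.index[inh]
                    G["reg_K"][i, j] = self.parameters[K]

        ch = self.dsb_channel
        rc = self.receptor_channel
        C = np.array([
            self.parameters[ch.k_per_gy],
            self.parameters[ch.k_background],
            self.parameters[ch.vmax_repair],
            self.parameters[ch.km_repair],
            self.parameters[rc.pool],
            self.parameters[rc.k_on],
            self.parameters[rc.k_off],
        ])
        inp = np.array([self.index[s] for s in self.input_species], dtype=np.int64)
        return P, G, C, inp


# ---------------------------------------------------------------------------
# right-hand side / transport evaluation (pure-python reference path)
# ---------------------------------------------------------------------------

def _term_rate(r, y, genes, dsb, rec, pars):
    k = pars[r.k]
    if r.kind == "const":
        return k
    if r.kind == "lin":
        return k * y[r.s1]
    if r.kind == "bilin":
        return k * y[r.s1] * y[r.s2]
    if r.kind == "mm":
        K = pars[r.K]
        return k * y[r.s1] * y[r.s2] / (K + y[r.s2])
    if r.kind == "lininh":
        K = pars[r.K]
        return k * y[r.s1] * K / (K + y[r.s2])
    if r.kind == "gene":
        return k * genes[r.gene]
    if r.kind == "dsblin":
        return k * dsb * y[r.s1]
    if r.kind == "reclin":
        return k * rec * y[r.s1]
    if r.kind == "sat":
        K = pars[r.K]
        return k * y[r.s1] / (K + y[r.s1])
    raise AssertionError(r.kind)


def rhs(state: CellState, spec: ModelSpec, *, only_transport=False,
        skip_transport=False):
    """Time derivative of the deterministic partition (molecules/s).

    Gene allele counts, the DSB count and the active receptor count enter
    as frozen discrete inputs.  ``only_transport`` / ``skip_transport``
    restrict the sum to cross-compartment shuttling terms (or everything
    but them), which is how the transport-antisymmetry contract is tested.
    """
    state.validate()
    y = {s.name: state.y[i] for i, s in enumerate(spec.species)}
    dy = np.zeros(spec.n_species)
    for r in spec.reactions:
        if only_transport and not r.transport:
            continue
        if skip_transport and r.transport:
            continue
        rate = _term_rate(r, y, state.genes, state.dsb,
                          state.receptors_active, spec.parameters)
        for sname, c in r.stoich:
            dy[spec.index[sname]] += c * rate
    for sname in spec.input_species:
        dy[spec.index[sname]] = 0.0   # inputs are protocol-controlled
    return dy


def transport_terms(state: CellState, spec: ModelSpec):
    """Contributions of cross-compartment transport terms only."""
    return rhs(state, spec, only_transport=True)


# ---------------------------------------------------------------------------
# default DDR model
# ---------------------------------------------------------------------------

def _species_table():
    S = Species
    return [
        S("tnf_e", "extracellular"),
        # p53 module
        S("p53_c", "cytoplasm"),
        S("p53_n", "nucleus"),
        S("p53a_n", "nucleus", "protein_phospho"),
        S("p53_mrna_c", "cytoplasm", "mRNA"),
        S("mdm2_c", "cytoplasm"),
        S("mdm2_n", "nucleus"),
        S("mdm2pp_n", "nucleus", "protein_multiphospho"),
        S("mdm2_mrna_c", "cytoplasm", "mRNA"),
        # ATM / MRN
        S("atm_n", "nucleus"),
        S("atma_n", "nucleus", "protein_phospho"),
        S("atm_mrna_c", "cytoplasm", "mRNA"),
        S("mrn_n", "nucleus", "complex"),
        S("mrn_act_n", "nucleus", "complex"),
        # Chk2
        S("chk2_n", "nucleus"),
        S("chk2a_n", "nucleus", "protein_phospho"),
        S("chk2_mrna_c", "cytoplasm", "mRNA"),
        # Wip1 and its regulators
        S("wip1_n", "nucleus"),
        S("wip1_mrna_c", "cytoplasm", "mRNA"),
        S("mir16_c", "cytoplasm", "miRNA"),
        S("ksrp_n", "nucleus"),
        S("ksrpa_n", "nucleus", "protein_phospho"),
        S("creb_n", "nucleus"),
        S("creba_n", "nucleus", "protein_phospho"),
        # NF-kB module
        S("nfkb_c", "cytoplasm"),
        S("nfkb_n", "nucleus"),
        S("ikb_c", "cytoplasm"),
        S("nfkb_ikb_c", "cytoplasm", "complex"),
        S("ikb_mrna_c", "cytoplasm", "mRNA"),
        S("ikk_c", "cytoplasm"),
        S("ikka_c", "cytoplasm", "protein_phospho"),
        S("a20_c", "cytoplasm"),
        S("a20_mrna_c", "cytoplasm", "mRNA"),
        # fate readouts
        S("p21_n", "nucleus"),
        S("p21_mrna_c", "cytoplasm", "mRNA"),
        S("bax_c", "cytoplasm"),
        S("bax_mrna_c", "cytoplasm", "mRNA"),
    ]


# Half-lives (hours) that define first-order degradation constants through
# rate = ln2 / t_half.  Measured-class values emulate cycloheximide /
# actinomycin D chase experiments on U2-OS; they are inputs, not fits.
HALF_LIVES_H = {
    "k_deg_p53m": 1.0,
    "k_deg_p53c": 1.9,
    "k_deg_mdm2m": 1.0,
    "k_deg_mdm2c": 1.1,
    "k_deg_mdm2n": 1.7,
    "k_deg_mdm2pp": 0.5,
    "k_deg_atmm": 1.6,
    "k_deg_atm": 9.6,
    "k_deg_mrn": 19.3,
    "k_deg_chk2m": 1.0,
    "k_deg_chk2": 6.4,
    "k_deg_wip1m": 0.8,
    "k_deg_wip1": 4.6,
    "k_deg_mir16": 1.9,
    "k_deg_ksrp": 19.3,
    "k_deg_creb": 19.3,
    "k_deg_ikbm": 0.7,
    "k_deg_ikb": 1.9,
    "k_deg_a20m": 0.7,
    "k_deg_a20": 1.9,
    "k_deg_p21m": 0.7,
    "k_deg_baxm": 1.0,
}


def _default_parameters():
    ln2 = np.log(2.0)

    pars = {k: ln2 / (v * 3600.0) for k, v in HALF_LIVES_H.items()}
    kinds = {k: "rate" for k in pars}

    def add(name, value, kind="rate"):
        pars[name] = value
        kinds[name] = kind

    # --- p53 module
    add("k_tc_p53_0", 0.01)
    add("k_tc_p53_nfkb", 3.5e-6)
    add("K_wip1_nfkb", 5.0e3, "K")       # Wip1 repression of NF-kB-dependent genes
    add("k_tl_p53", 0.1)
    add("k_deg_p53_mdm2c", 3.0e-8)
    add("k_imp_p53", 3.0e-4)
    add("k_deg_p53n", 2.0e-5)
    add("k_deg_p53_mdm2n", 4.0e-8)
    add("k_act_p53_atm", 5.0e-3)
    add("k_act_p53_chk2", 8.0e-4)
    add("K_p53_act", 2.0e4, "K")
    add("k_deact_p53_wip1", 8.0e-3)
    add("K_p53_deact", 1.0e4, "K")
    add("k_deact_p53_0", 2.0e-3)
    add("k_deg_p53a_mdm2n", 4.0e-8)
    add("k_deg_p53a", 6.0e-5)
    # --- Mdm2
    add("k_tc_mdm2_0", 0.003)
    add("k_tc_mdm2_p53", 4.0e-6)
    add("k_tl_mdm2", 0.06)
    add("k_imp_mdm2", 1.5e-4)
    add("k_imp_mdm2_atm", 1.5e-7)
    add("k_ph_mdm2_atm", 1.2e-3)
    add("K_mdm2_ph", 1.0e4, "K")
    add("k_deph_mdm2_wip1", 6.0e-3)
    # --- ATM / MRN
    add("k_tc_atm", 0.005)
    add("k_tl_atm", 0.02)
    add("k_syn_mrn", 0.1)
    add("k_act_mrn", 2.0e-4)
    add("k_deact_mrn", 3.0e-3)
    add("k_act_atm", 5.0e-3)
    add("k_auto_atm", 0.0)
    add("K_atm_act", 2.0e4, "K")
    add("k_deact_atm_wip1", 3.0e-4)
    add("K_atm_deact", 1.0e4, "K")
    add("vd_deact_atm", 0.5)
    add("K_deact_atm_sat", 100.0, "K")
    # --- Chk2
    add("k_tc_chk2", 0.004)
    add("k_tl_chk2", 0.02)
    add("k_act_chk2", 1.0e-3)
    add("K_chk2_act", 1.0e4, "K")
    add("k_deact_chk2_wip1", 3.0e-3)
    add("K_chk2_deact", 1.0e4, "K")
    add("k_deact_chk2_0", 5.0e-4)
    # --- Wip1 / miR-16 / KSRP / CREB
    add("k_tc_wip1", 0.02)
    add("k_deg_wip1m_mir", 1.0e-8)
    add("k_tl_wip1", 1.3e-2)
    add("k_syn_mir16_0", 0.05)
    add("k_syn_mir16_ksrp", 4.0e-4)
    add("k_syn_ksrp", 0.1)
    add("k_act_ksrp", 2.0e-4)
    add("K_ksrp_act", 1.0e4, "K")
    add("k_deact_ksrp", 1.0e-3)
    add("k_syn_creb", 0.1)
    add("k_act_creb", 2.0e-4)
    add("K_creb_act", 1.0e4, "K")
    add("k_deact_creb", 1.0e-3)
    # --- NF-kB module
    add("k_tc_ikb_0", 0.002)
    add("k_tc_ikb_nfkb", 3.0e-6)
    add("k_tl_ikb", 0.1)
    add("k_ph_ikb", 2.0e-8)
    add("k_b_nfkb_ikb", 1.0e-6)
    add("k_rel_nfkb", 3.0e-8)
    add("k_deg_nfkb_ikb", 5.0e-6)
    add("k_syn_nfkb", 0.3)
    add("k_deg_nfkb", 5.0e-6)
    add("k_imp_nfkb", 5.0e-4)
    add("k_exp_nfkb", 1.0e-6)
    add("k_syn_ikk", 0.15)
    add("k_deg_ikk", 1.0e-5)
    add("k_act_ikk_rec", 1.0e-5)
    add("k_act_ikk_atm", 3.0e-9)
    add("k_inact_ikk", 3.0e-4)
    add("k_inact_ikk_a20", 1.0e-8)
    add("k_tc_a20_0", 2.0e-4)
    add("k_tc_a20_nfkb", 3.0e-6)
    add("k_tl_a20", 0.1)
    # --- p21 / Bax
    add("k_tc_p21", 0.01)
    add("k_tl_p21", 6.7e-3)
    add("k_deg_p21", 4.0e-6)
    add("k_tc_bax", 0.006)
    add("k_tl_bax", 2.0e-2)
    add("k_deg_bax", 6.0e-6)
    # --- gene switching
    add("q0_wip1", 2.5e-6)
    add("q_wip1_p53", 4.0e-7)
    add("q_wip1_creb", 2.0e-7)
    add("q_wip1_nfkb", 8.0e-8)
    add("K_wip1_auto", 3.0e3, "K")
    add("d_wip1", 6.0e-4)
    add("q0_chk2", 1.0e-4)
    add("q_chk2_p53", 1.0e-6)
    add("K_chk2_p53rep", 1.0e4, "K")
    add("d_chk2", 3.0e-4)
    add("q0_atm", 1.0e-4)
    add("q_atm_creb", 2.0e-7)
    add("d_atm", 2.0e-4)
    add("q0_p21", 1.0e-7)
    add("q_p21_p53", 8.0e-7)
    add("K_p21_act", 8.0e2, "K")
    add("d_p21", 1.0e-3)
    add("q0_bax", 8.0e-8)
    add("q_bax_p53", 1.1e-6)
    add("K_bax_act", 6.0e2, "K")
    add("d_bax", 6.0e-4)
    # --- stochastic damage / receptor channels
    add("dsb_per_gy", 35.0, "per_gy")
    add("k_dsb_bg", 2.2e-5)
    add("vmax_repair", 6.5e-3)
    add("km_repair", 20.0, "count")
    add("n_receptors", 200.0, "count")
    add("k_rec_on", 1.2e-4)              # per receptor per (ng/ml) per s
    add("k_rec_off", 3.0e-4)

    return pars, kinds


#: parameters fitted to the training set (everything else is a measured
#: half-life, a literature synthesis limit, or a structural constant)
FITTED_PARAMETERS = (
    "vmax_repair",
    "k_dsb_bg",
    "k_act_atm",
    "k_deact_atm_wip1",
    "k_auto_atm",
    "k_act_p53_atm",
    "k_deact_p53_wip1",
    "q_wip1_p53",
    "q_wip1_nfkb",
    "k_act_ikk_atm",
    "k_tc_p53_nfkb",
    "q_p21_p53",
    "q_bax_p53",
)


def _reaction_table():
    R = Reaction
    t = []

    # --- p53 module
    t += [
        R("p53 mRNA constitutive transcription", "const", "k_tc_p53_0",
          stoich=(("p53_mrna_c", 1),)),
        R("p53 mRNA NF-kB-dependent transcription (Wip1-repressed)", "lininh",
          "k_tc_p53_nfkb", s1="nfkb_n", s2="wip1_n", K="K_wip1_nfkb",
          stoich=(("p53_mrna_c", 1),)),
        R("p53 mRNA degradation", "lin", "k_deg_p53m", s1="p53_mrna_c",
          stoich=(("p53_mrna_c", -1),)),
        R("p53 translation", "lin", "k_tl_p53", s1="p53_mrna_c",
          stoich=(("p53_c", 1),)),
        R("cytoplasmic p53 degradation", "lin", "k_deg_p53c", s1="p53_c",
          stoich=(("p53_c", -1),)),
        R("cytoplasmic p53 Mdm2-mediated degradation", "bilin",
          "k_deg_p53_mdm2c", s1="p53_c", s2="mdm2_c", stoich=(("p53_c", -1),)),
        R("p53 nuclear import", "lin", "k_imp_p53", s1="p53_c",
          stoich=(("p53_c", -1), ("p53_n", 1)), transport=True),
        R("nuclear p53 degradation", "lin", "k_deg_p53n", s1="p53_n",
          stoich=(("p53_n", -1),)),
        R("nuclear p53 Mdm2-mediated degradation", "bilin", "k_deg_p53_mdm2n",
          s1="p53_n", s2="mdm2_n", stoich=(("p53_n", -1),)),
        R("p53 phosphorylation by ATM", "mm", "k_act_p53_atm",
          s1="atma_n", s2="p53_n", K="K_p53_act",
          stoich=(("p53_n", -1), ("p53a_n", 1))),
        R("p53 phosphorylation by Chk2", "mm", "k_act_p53_chk2",
          s1="chk2a_n", s2="p53_n", K="K_p53_act",
          stoich=(("p53_n", -1), ("p53a_n", 1))),
        R("active p53 dephosphorylation by Wip1", "mm", "k_deact_p53_wip1",
          s1="wip1_n", s2="p53a_n", K="K_p53_deact",
          stoich=(("p53a_n", -1), ("p53_n", 1))),
        R("active p53 spontaneous dephosphorylation", "lin", "k_deact_p53_0",
          s1="p53a_n", stoich=(("p53a_n", -1), ("p53_n", 1))),
        R("active p53 Mdm2-mediated degradation", "bilin", "k_deg_p53a_mdm2n",
          s1="p53a_n", s2="mdm2_n", stoich=(("p53a_n", -1),)),
        R("active p53 degradation", "lin", "k_deg_p53a", s1="p53a_n",
          stoich=(("p53a_n", -1),)),
    ]

    # --- Mdm2 (merged Mdm2/MdmX)
    t += [
        R("Mdm2 mRNA constitutive transcription", "const", "k_tc_mdm2_0",
          stoich=(("mdm2_mrna_c", 1),)),
        R("Mdm2 mRNA p53-dependent transcription", "lin", "k_tc_mdm2_p53",
          s1="p53a_n", stoich=(("mdm2_mrna_c", 1),)),
        R("Mdm2 mRNA degradation", "lin", "k_deg_mdm2m", s1="mdm2_mrna_c",
          stoich=(("mdm2_mrna_c", -1),)),
        R("Mdm2 translation", "lin", "k_tl_mdm2", s1="mdm2_mrna_c",
          stoich=(("mdm2_c", 1),)),
        R("cytoplasmic Mdm2 degradation", "lin", "k_deg_mdm2c", s1="mdm2_c",
          stoich=(("mdm2_c", -1),)),
        R("Mdm2 nuclear import", "lin", "k_imp_mdm2", s1="mdm2_c",
          stoich=(("mdm2_c", -1), ("mdm2_n", 1)), transport=True),
        R("ATM-stimulated Mdm2 nuclear import", "bilin", "k_imp_mdm2_atm",
          s1="mdm2_c", s2="atma_n",
          stoich=(("mdm2_c", -1), ("mdm2_n", 1)), transport=True),
        R("nuclear Mdm2 degradation", "lin", "k_deg_mdm2n", s1="mdm2_n",
          stoich=(("mdm2_n", -1),)),
        R("Mdm2 multi-phosphorylation by ATM", "mm", "k_ph_mdm2_atm",
          s1="atma_n", s2="mdm2_n", K="K_mdm2_ph",
          stoich=(("mdm2_n", -1), ("mdm2pp_n", 1))),
        R("multi-phospho Mdm2 dephosphorylation by Wip1", "mm",
          "k_deph_mdm2_wip1", s1="wip1_n", s2="mdm2pp_n", K="K_mdm2_ph",
          stoich=(("mdm2pp_n", -1), ("mdm2_n", 1))),
        R("multi-phospho Mdm2 degradation", "lin", "k_deg_mdm2pp",
          s1="mdm2pp_n", stoich=(("mdm2pp_n", -1),)),
    ]

    # --- ATM / MRN
    t += [
        R("ATM transcription (CREB-regulated gene)", "gene", "k_tc_atm",
          gene="atm", stoich=(("atm_mrna_c", 1),)),
        R("ATM mRNA degradation", "lin", "k_deg_atmm", s1="atm_mrna_c",
          stoich=(("atm_mrna_c", -1),)),
        R("ATM translation", "lin", "k_tl_atm", s1="atm_mrna_c",
          stoich=(("atm_n", 1),)),
        R("ATM degradation", "lin", "k_deg_atm", s1="atm_n",
          stoich=(("atm_n", -1),)),
        R("active ATM degradation", "lin", "k_deg_atm", s1="atma_n",
          stoich=(("atma_n", -1),)),
        R("MRN synthesis", "const", "k_syn_mrn", stoich=(("mrn_n", 1),)),
        R("MRN degradation", "lin", "k_deg_mrn", s1="mrn_n",
          stoich=(("mrn_n", -1),)),
        R("active MRN degradation", "lin", "k_deg_mrn", s1="mrn_act_n",
          stoich=(("mrn_act_n", -1),)),
        R("MRN activation at DSB sites", "dsblin", "k_act_mrn", s1="mrn_n",
          stoich=(("mrn_n", -1), ("mrn_act_n", 1))),
        R("active MRN deactivation", "lin", "k_deact_mrn", s1="mrn_act_n",
          stoich=(("mrn_act_n", -1), ("mrn_n", 1))),
        R("ATM activation by active MRN", "mm", "k_act_atm",
          s1="mrn_act_n", s2="atm_n", K="K_atm_act",
          stoich=(("atm_n", -1), ("atma_n", 1))),
        # trans-autophosphorylation makes ATM activity excitable: once
        # ignited by damage it relaxes slowly, at a rate set by Wip1
        R("ATM trans-autophosphorylation", "mm", "k_auto_atm",
          s1="atma_n", s2="atm_n", K="K_atm_act",
          stoich=(("atm_n", -1), ("atma_n", 1))),
        R("active ATM dephosphorylation by Wip1", "mm", "k_deact_atm_wip1",
          s1="wip1_n", s2="atma_n", K="K_atm_deact",
          stoich=(("atma_n", -1), ("atm_n", 1))),
        # constitutive ATM-directed phosphatase has fixed capacity; its
        # saturation at high ATM activity makes the damage response
        # excitable, with Wip1 setting the switch-off rate
        R("active ATM constitutive dephosphorylation (saturable)", "sat",
          "vd_deact_atm", s1="atma_n", K="K_deact_atm_sat",
          stoich=(("atma_n", -1), ("atm_n", 1))),
    ]

    # --- Chk2
    t += [
        R("Chk2 transcription", "gene", "k_tc_chk2", gene="chk2",
          stoich=(("chk2_mrna_c", 1),)),
        R("Chk2 mRNA degradation", "lin", "k_deg_chk2m", s1="chk2_mrna_c",
          stoich=(("chk2_mrna_c", -1),)),
        R("Chk2 translation", "lin", "k_tl_chk2", s1="chk2_mrna_c",
          stoich=(("chk2_n", 1),)),
        R("Chk2 degradation", "lin", "k_deg_chk2", s1="chk2_n",
          stoich=(("chk2_n", -1),)),
        R("active Chk2 degradation", "lin", "k_deg_chk2", s1="chk2a_n",
          stoich=(("chk2a_n", -1),)),
        R("Chk2 phosphorylation by ATM", "mm", "k_act_chk2",
          s1="atma_n", s2="chk2_n", K="K_chk2_act",
          stoich=(("chk2_n", -1), ("chk2a_n", 1))),
        R("active Chk2 dephosphorylation by Wip1", "mm", "k_deact_chk2_wip1",
          s1="wip1_n", s2="chk2a_n", K="K_chk2_deact",
          stoich=(("chk2a_n", -1), ("chk2_n", 1))),
        R("active Chk2 spontaneous deactivation", "lin", "k_deact_chk2_0",
          s1="chk2a_n", stoich=(("chk2a_n", -1), ("chk2_n", 1))),
    ]

    # --- Wip1 / miR-16 / KSRP / CREB
    t += [
        R("Wip1 transcription", "gene", "k_tc_wip1", gene="wip1",
          stoich=(("wip1_mrna_c", 1),)),
        R("Wip1 mRNA degradation", "lin", "k_deg_wip1m", s1="wip1_mrna_c",
          stoich=(("wip1_mrna_c", -1),)),
        R("Wip1 mRNA miR-16-mediated degradation", "bilin", "k_deg_wip1m_mir",
          s1="wip1_mrna_c", s2="mir16_c", stoich=(("wip1_mrna_c", -1),)),
        R("Wip1 translation", "lin", "k_tl_wip1", s1="wip1_mrna_c",
          stoich=(("wip1_n", 1),)),
        R("Wip1 degradation", "lin", "k_deg_wip1", s1="wip1_n",
          stoich=(("wip1_n", -1),)),
        R("miR-16 constitutive biogenesis", "const", "k_syn_mir16_0",
          stoich=(("mir16_c", 1),)),
        R("miR-16 KSRP-promoted biogenesis", "lin", "k_syn_mir16_ksrp",
          s1="ksrpa_n", stoich=(("mir16_c", 1),)),
        R("miR-16 degradation", "lin", "k_deg_mir16", s1="mir16_c",
          stoich=(("mir16_c", -1),)),
        R("KSRP synthesis", "const", "k_syn_ksrp", stoich=(("ksrp_n", 1),)),
        R("KSRP degradation", "lin", "k_deg_ksrp", s1="ksrp_n",
          stoich=(("ksrp_n", -1),)),
        R("active KSRP degradation", "lin", "k_deg_ksrp", s1="ksrpa_n",
          stoich=(("ksrpa_n", -1),)),
        R("KSRP phosphorylation by ATM", "mm", "k_act_ksrp",
          s1="atma_n", s2="ksrp_n", K="K_ksrp_act",
          stoich=(("ksrp_n", -1), ("ksrpa_n", 1))),
        R("active KSRP deactivation", "lin", "k_deact_ksrp", s1="ksrpa_n",
          stoich=(("ksrpa_n", -1), ("ksrp_n", 1))),
        R("CREB synthesis", "const", "k_syn_creb", stoich=(("creb_n", 1),)),
        R("CREB degradation", "lin", "k_deg_creb", s1="creb_n",
          stoich=(("creb_n", -1),)),
        R("active CREB degradation", "lin", "k_deg_creb", s1="creba_n",
          stoich=(("creba_n", -1),)),
        R("CREB phosphorylation by ATM", "mm", "k_act_creb",
          s1="atma_n", s2="creb_n", K="K_creb_act",
          stoich=(("creb_n", -1), ("creba_n", 1))),
        R("active CREB deactivation", "lin", "k_deact_creb", s1="creba_n",
          stoich=(("creba_n", -1), ("creb_n", 1))),
    ]

    # --- NF-kB module
    t += [
        R("IkB mRNA constitutive transcription", "const", "k_tc_ikb_0",
          stoich=(("ikb_mrna_c", 1),)),
        R("IkB mRNA NF-kB-dependent transcription (Wip1-repressed)", "lininh",
          "k_tc_ikb_nfkb", s1="nfkb_n", s2="wip1_n", K="K_wip1_nfkb",
          stoich=(("ikb_mrna_c", 1),)),
        R("IkB mRNA degradation", "lin", "k_deg_ikbm", s1="ikb_mrna_c",
          stoich=(("ikb_mrna_c", -1),)),
        R("IkB translation", "lin", "k_tl_ikb", s1="ikb_mrna_c",
          stoich=(("ikb_c", 1),)),
        R("free IkB degradation", "lin", "k_deg_ikb", s1="ikb_c",
          stoich=(("ikb_c", -1),)),
        R("free IkB IKK-mediated degradation", "bilin", "k_ph_ikb",
          s1="ikb_c", s2="ikka_c", stoich=(("ikb_c", -1),)),
        R("NF-kB:IkB association", "bilin", "k_b_nfkb_ikb",
          s1="nfkb_c", s2="ikb_c",
          stoich=(("nfkb_c", -1), ("ikb_c", -1), ("nfkb_ikb_c", 1))),
        R("IKK-mediated NF-kB release from IkB", "bilin", "k_rel_nfkb",
          s1="nfkb_ikb_c", s2="ikka_c",
          stoich=(("nfkb_ikb_c", -1), ("nfkb_c", 1))),
        R("NF-kB:IkB complex degradation", "lin", "k_deg_nfkb_ikb",
          s1="nfkb_ikb_c", stoich=(("nfkb_ikb_c", -1),)),
        R("NF-kB synthesis", "const", "k_syn_nfkb", stoich=(("nfkb_c", 1),)),
        R("cytoplasmic NF-kB degradation", "lin", "k_deg_nfkb", s1="nfkb_c",
          stoich=(("nfkb_c", -1),)),
        R("nuclear NF-kB degradation", "lin", "k_deg_nfkb", s1="nfkb_n",
          stoich=(("nfkb_n", -1),)),
        R("NF-kB nuclear import", "lin", "k_imp_nfkb", s1="nfkb_c",
          stoich=(("nfkb_c", -1), ("nfkb_n", 1)), transport=True),
        R("IkB-mediated NF-kB nuclear export and resequestration", "bilin",
          "k_exp_nfkb", s1="nfkb_n", s2="ikb_c",
          stoich=(("nfkb_n", -1), ("ikb_c", -1), ("nfkb_ikb_c", 1))),
        R("IKK synthesis", "const", "k_syn_ikk", stoich=(("ikk_c", 1),)),
        R("IKK degradation", "lin", "k_deg_ikk", s1="ikk_c",
          stoich=(("ikk_c", -1),)),
        R("active IKK degradation", "lin", "k_deg_ikk", s1="ikka_c",
          stoich=(("ikka_c", -1),)),
        R("IKK activation by TNF receptors", "reclin", "k_act_ikk_rec",
          s1="ikk_c", stoich=(("ikk_c", -1), ("ikka_c", 1))),
        R("IKK activation by ATM (genotoxic arm)", "bilin", "k_act_ikk_atm",
          s1="ikk_c", s2="atma_n", stoich=(("ikk_c", -1), ("ikka_c", 1))),
        R("active IKK spontaneous inactivation", "lin", "k_inact_ikk",
          s1="ikka_c", stoich=(("ikka_c", -1), ("ikk_c", 1))),
        R("active IKK A20-mediated inactivation", "bilin", "k_inact_ikk_a20",
          s1="ikka_c", s2="a20_c", stoich=(("ikka_c", -1), ("ikk_c", 1))),
        R("A20 mRNA constitutive transcription", "const", "k_tc_a20_0",
          stoich=(("a20_mrna_c", 1),)),
        R("A20 mRNA NF-kB-dependent transcription (Wip1-repressed)", "lininh",
          "k_tc_a20_nfkb", s1="nfkb_n", s2="wip1_n", K="K_wip1_nfkb",
          stoich=(("a20_mrna_c", 1),)),
        R("A20 mRNA degradation", "lin", "k_deg_a20m", s1="a20_mrna_c",
          stoich=(("a20_mrna_c", -1),)),
        R("A20 translation", "lin", "k_tl_a20", s1="a20_mrna_c",
          stoich=(("a20_c", 1),)),
        R("A20 degradation", "lin", "k_deg_a20", s1="a20_c",
          stoich=(("a20_c", -1),)),
    ]

    # --- p21 / Bax fate readouts
    t += [
        R("p21 transcription", "gene", "k_tc_p21", gene="p21",
          stoich=(("p21_mrna_c", 1),)),
        R("p21 mRNA degradation", "lin", "k_deg_p21m", s1="p21_mrna_c",
          stoich=(("p21_mrna_c", -1),)),
        R("p21 translation", "lin", "k_tl_p21", s1="p21_mrna_c",
          stoich=(("p21_n", 1),)),
        R("p21 degradation", "lin", "k_deg_p21", s1="p21_n",
          stoich=(("p21_n", -1),)),
        R("Bax transcription", "gene", "k_tc_bax", gene="bax",
          stoich=(("bax_mrna_c", 1),)),
        R("Bax mRNA degradation", "lin", "k_deg_baxm", s1="bax_mrna_c",
          stoich=(("bax_mrna_c", -1),)),
        R("Bax translation", "lin", "k_tl_bax", s1="bax_mrna_c",
          stoich=(("bax_c", 1),)),
        R("Bax degradation", "lin", "k_deg_bax", s1="bax_c",
          stoich=(("bax_c", -1),)),
    ]
    return t


def _gene_table():
    G = GeneDef
    return [
        # Wip1 gene: activated by p53, CREB and NF-kB; the NF-kB arm is
        # self-inhibited by the Wip1 protein itself.
        G("wip1", basal="q0_wip1", deactivation_rate="d_wip1",
          regulators=(
              ("p53a_n", "q_wip1_p53", None, None),
              ("creba_n", "q_wip1_creb", None, None),
              ("nfkb_n", "q_wip1_nfkb", "wip1_n", "K_wip1_auto"),
          )),
        # Chk2 gene: p53-proportional activation carrying a p53-dependent
        # inhibition factor (p53 also represses Chk2 transcription).
        G("chk2", basal="q0_chk2", deactivation_rate="d_chk2",
          regulators=(
              ("p53a_n", "q_chk2_p53", "p53a_n", "K_chk2_p53rep"),
          )),
        G("atm", basal="q0_atm", deactivation_rate="d_atm",
          regulators=(("creba_n", "q_atm_creb", None, None),)),
        G("p21", basal="q0_p21", deactivation_rate="d_p21",
          regulators=(("p53a_n", "q_p21_p53", "p53a_n", "K_p21_act"),)),
        G("bax", basal="q0_bax", deactivation_rate="d_bax",
          regulators=(("p53a_n", "q_bax_p53", "p53a_n", "K_bax_act"),)),
    ]


def build_default_model() -> ModelSpec:
    """Assemble the default U2-OS DDR model.

    Raises :class:`ModelLoadError` naming the offending symbol if any
    reaction references an undeclared species or parameter.
    """
    pars, kinds = _default_parameters()
    return ModelSpec(
        species=_species_table(),
        parameters=pars,
        reactions=_reaction_table(),
        genes=_gene_table(),
        dsb_channel=DsbChannel(),
        receptor_channel=ReceptorChannel(),
        param_kinds=kinds,
        fitted=FITTED_PARAMETERS,
    )


# ---------------------------------------------------------------------------
# resting state
# ---------------------------------------------------------------------------

def mean_field_resting_state(spec: ModelSpec, *, t_relax=3.0e6, dt=50.0,
                             polish=True):
    """Locate the unstressed fixed point of the mean-field system.

    Gene states are treated as continuous means (d g/dt = a(y) (2-g) - d g),
    the DSB count as its deterministic mean under the background induction /
    saturating repair balance, and TNF receptors as all inactive.  The
    system is relaxed by integration and then polished by root-finding.

    Returns a :class:`CellState` (with fractional gene/dsb entries stored
    separately) -- specifically ``(y, g_mean, dsb_mean)``.
    """
    from . import engine  # deferred: engine imports this module's pack format

    y, g, dsb = engine.relax_mean_field(spec, t_relax=t_relax, dt=dt)
    if polish:
        from scipy.optimize import root

        n, ng = spec.n_species, spec.n_genes
        packed = spec.pack()

        inp_idx = [self_idx for self_idx in
                   (spec.index[s] for s in spec.input_species)]

        def fun(z):
            yy = z[:n]
            gg = z[n:n + ng]
            dd = z[n + ng]
            res = engine.mean_field_rhs(packed, yy, gg, dd, 0.0, 0.0, 0.0)
            for i in inp_idx:
                res[i] = yy[i]          # pin protocol-controlled inputs at 0
            return res

        z0 = np.concatenate([y, g, [dsb]])
        sol = root(fun, z0, method="hybr", options={"xtol": 1e-12})
        if sol.success and np.all(sol.x[:n] >= -1e-6):
            z = np.clip(sol.x, 0.0, None)
            y, g, dsb = z[:n], z[n:n + ng], float(z[n + ng])
    return y, g, dsb


def resting_state(spec: ModelSpec):
    """Cached mean-field resting state ``(y, gene_means, dsb_mean)``."""
    if spec._resting is None:
        spec._resting = mean_field_resting_state(spec)
    return spec._resting
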