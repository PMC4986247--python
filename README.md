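# ddrsim

Hybrid stochastic–deterministic simulator of the ATM/p53/NF-κB/Wip1
DNA-damage-response network in single mammalian cells (parameterised for
the U2-OS osteosarcoma line), for researchers studying how the Wip1
phosphatase gates the choice between cell-cycle arrest, apoptosis and
clonogenic survival after ionizing radiation (IR) and TNFα exposure.

## The model

A cell is a set of molecule counts across three well-mixed compartments
(extracellular matrix, cytoplasm, nucleus).  Double-strand breaks (DSBs)
are discrete: they appear with propensity `a_DSB = y·Ḋ(t) + a₀`
(`y` ≈ 35 DSB/Gy, dose rate `Ḋ` in Gy/s, spontaneous background `a₀`)
and are repaired with a repair-complex-limited propensity
`v_max·D/(K_m + D)`.  DSBs activate the MRN complex and ATM; active ATM
drives p53 (directly and via Chk2), inactivates nuclear Mdm2 by
multi-phosphorylation, and feeds the NF-κB module through IKK.  Wip1 —
transcriptionally induced by p53, CREB and NF-κB, repressed
post-transcriptionally by miR-16 — dephosphorylates ATM, Chk2, p53 and
Mdm2, switching the response off.  p21 and Bax report arrest and
apoptosis.

Numerics follow the Haseltine–Rawlings partitioning: protein/mRNA levels
are integrated with fixed-step RK4; gene allele switching (each gene has
two alleles, state g ∈ {0,1,2}, activation propensity
`(q₀ + Σᵢ qᵢ·TFᵢ)·(2−g)`, spontaneous deactivation `d·g`), DSB events and
TNF receptor flips fire through the direct Gillespie method, with
propensities frozen over each deterministic step window.

Cell fate uses the two-threshold rule: arrest while p21 ≥ θ_p21;
apoptosis at the first instant active p53 ≥ θ_p53 **and** Bax ≥ θ_Bax
simultaneously; a cell is clonogenically non-viable if it dies before its
first division or accumulates more than 63.9 h of arrest.

See `docs/methods.md` for assumptions, parameter provenance and
limitations.

## Worked example

```python
import ddrsim

spec = ddrsim.build_default_model()              # wild-type U2-OS model
kd   = ddrsim.apply_knockdown(spec, "wip1", 0.25)  # Wip1-RNAi (~25 %)

prot = ddrsim.make_protocol("ir_only", dose=10.0, horizon_h=36.0)
cfg  = ddrsim.EngineConfig(dt=4.0, save_every=600.0)

res = ddrsim.run_population(spec, prot, n=200, master_seed=1, cfg=cfg)
print("Wip1 protein peak: %.1f h" % res.peak_time_h("wip1_n"))
print("Wip1 mRNA peak:    %.1f h" % res.peak_time_h("wip1_mrna_c"))
print(res.summary())
```

prints (exact fractions vary with the seed):

```
Wip1 protein peak: 18.2 h
Wip1 mRNA peak:    2.5 h
{'n': 200, 'apoptotic_pct_0_24h': 2.0, 'apoptotic_pct_24_48h': 0.0,
 'survival_pct': 98.0}
```

i.e. after 10 Gy the median cell's Wip1 mRNA spikes at ~2–3 h and the
protein accumulates to a maximum at ~18 h (the switch-off of the
response); a small percentage of cells pass the joint p53/Bax apoptosis
threshold, and survival over this 36 h horizon is still high — colony
loss at 10 Gy builds up through long arrests, which a 120 h horizon
captures (`horizon_h=120`).  A command-line interface wraps the same
machinery:

```bash
ddrsim simulate --protocol ir_only --dose 10 --n 200 --seed 42 --out run.h5
ddrsim selftest
```

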