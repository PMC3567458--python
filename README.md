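# raasim

Whole-body, physiologically based simulation of the circulating
renin–angiotensin–aldosterone system (RAAS) and its inhibition by oral
enalapril.

## What this is for

The RAAS is the endocrine cascade behind blood-pressure regulation and
one of pharmacology's most-targeted systems: renin cleaves hepatically
secreted angiotensinogen (AGT) to angiotensin 1 (Ang1), endothelial
angiotensin-converting enzyme (ACE) converts Ang1 to angiotensin 2
(Ang2), Ang2 binds the AT1 receptor, the receptor complex drives
aldosterone secretion, and Ang2 feedback-inhibits the renal activation of
prorenin to renin.  `raasim` is for modellers who want a mechanistic,
compartment-resolved sandbox for this system: it couples the hormone
cascade to a reduced whole-body physiology (17 plasma compartments
linked by blood flow, with membrane-bound ACE/AT1 pools placed by
relative organ expression), adds a parent–metabolite PK model of the
prodrug enalapril (Ena) and its active metabolite enalaprilat (Enaat),
and represents the drug's mode of action explicitly: reversible
stoichiometric sequestration of ACE by Enaat.

The core quantitative machinery, in the field's standard notation:

* convective transport `r = Q_organ (1 − HCT) C_pls`;
* Michaelis–Menten conversions `r = k_cat V0 C0 C_pro/(C_pro + K_m)`;
* first-order degradation `r = C ln2 / t_1/2` per plasma litre;
* receptor/enzyme binding `r = k⁺C0C2 − k⁻C_complex`;
* feedback-inhibited prorenin activation
  `r = V_MaxKid V_Kidney C_pro/(C_pro + K_mKid(1 + C_Ang2/K_inh))`;
* hepatic carboxylesterase hydrolysis
  `r = V_maxLiv V_Liver C_Ena/(C_Ena + K_mLiv)`;
* steady-state construction (stiff integration + Newton polish),
  exact dose-event handling, Nelder–Mead simplex identification of the
  cascade parameters against steady-state targets, and seeded
  random-search identification of the absorption parameters against
  concentration–time data.

All default kinetic constants, study populations and expression
percentages ship as plain data files (`src/raasim/data/`).

## Worked example

```bash
python examples/02_oral_enalapril.py
```

prints

```
venous concentrations (umol/L), pre-dose vs 4 h post-dose:
  renin         4.904e-06 ->  5.015e-06  (  +2.3%)
  Ang1          1.502e-05 ->  1.574e-05  (  +4.8%)
  Ang2          8.684e-07 ->  6.970e-07  ( -19.7%)
  aldosterone   5.584e-02 ->  5.242e-02  (  -6.1%)
peak venous Enaat: 7.374e-01 umol/L (ACE Kd = 6.11e-04 umol/L)
```

Reading it: 10 mg oral Ena at t = 1500 min is absorbed, hydrolysed in
the liver to Enaat, and Enaat (peaking three orders of magnitude above
its ACE dissociation constant) occupies the ACE pool.  Blocked Ang1→Ang2
conversion drops Ang2 and, downstream, aldosterone; the broken negative
feedback on prorenin activation raises renin and with it Ang1 — the
classic ACE-inhibitor signature.  (This run uses the shipped rate
constants directly; `examples/03_identify_cascade.py` shows the
identification step that aligns the baseline steady state with the
published venous concentrations, and `examples/04_fit_absorption.py`
the random-search recovery of the absorption parameters from synthetic
noisy data.)

The same scenarios are scriptable from a shell:

```bash
raasim steady-state
raasim simulate --study Biollaz --out-dir out/
raasim fit --mode simplex --out-dir out/
raasim fixtures --kind pk_curves -n 3 --seed 1
```

## Layout

* `src/raasim/physiology.py` — body graph, expression scaling, subjects
* `src/raasim/kinetics.py` — cascade rate laws and parameter containers
* `src/raasim/drug.py` — Ena/Enaat properties, absorption, clearances
* `src/raasim/simulator.py` — ODE assembly, steady state, dosing
* `src/raasim/identification.py` — RMS objective, simplex, Monte Carlo
* `src/raasim/io.py`, `src/raasim/cli.py` — configs, fixtures, CLI
* `docs/methods.md` — model assumptions, numerics and design decisions
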