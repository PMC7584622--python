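# dcache-ai2

Tools for finding candidate autoinducer-2 (AI-2) receptors among
dCache_1 sensor domains, and for analysing the isothermal titration
calorimetry (ITC) experiments that validate them.

AI-2 is an interspecies quorum-sensing signal. Its classical receptors
(LuxP, LsrB) are absent from many bacteria that nonetheless respond to
AI-2; a third receptor type is the extracytoplasmic dCache_1 domain, as
found in the *Pseudomonas aeruginosa* chemoreceptor PctA. The hallmark
of the AI-2-binding dCache_1 subfamily is the joint conservation of
five pocket residues — **R126, W128, Y144, D146, D173** in PctA
numbering (the "RWYDD" signature) inside the ligand-binding domain
(residues 36–261, active pocket 100–175).

This package is for computational microbiologists who want to screen a
domain-family alignment for that signature, and for anyone fitting
one-site binding isotherms to per-injection ITC heats.

## What it does

- **Reference anchoring** — map multiple-alignment columns (or pairwise
  alignments, BLOSUM62 / gap open 11 / extend 1) onto PctA residue
  numbering so pocket positions are comparable across sequences.
- **Signature screening** — count, per sequence, how many of the five
  pocket positions carry the reference residue; select members matching
  ≥ k of 5 (strict identity; gaps and X are mismatches).
- **Conservation profiling** — position-frequency matrices over the
  pocket region and sequence-logo information content,
  IC(j) = log₂20 − H(j) bits.
- **Domain-architecture classification** — assign each protein to MCP,
  HK, CSP (GGDEF/EAL/HD-GYP), SP, STK, AC/GC, CNB-only or
  UNCHARACTERIZED from its Pfam output domains, with an editable YAML
  rule table, and roll up counts by class and phylum.
- **One-site ITC model** — forward simulation of per-injection heats
  with the displacement recursion
  `M_i = M_{i-1}(1 - v_i/V0)`, `L_i = L_{i-1}(1 - v_i/V0) + Ls v_i/V0`,
  bound complex from the binding quadratic
  `[PL] = ((nM + L + Kd) − √((nM + L + Kd)² − 4 nM L))/2`,
  heat `q_i = ΔH·V0·([PL]_i − [PL]_{i-1}(1 − v_i/V0)) + q₀`;
  heat-of-dilution correction; multi-start nonlinear least-squares
  fitting of (Kd, n, ΔH, q₀) with log-parameterized Kd and optional
  fixed stoichiometry; Wiseman c = n·M₀/Kd diagnostics.
- **Assay metrics** — chemotaxis response index RI = D1/(D1+D2)
  (RI > 0.52 scores chemotaxis), buffer-corrected capillary counts,
  fold induction, optimal dose.
- **Synthetic-data generators** — aligned families with a planted
  signature at exact prevalence, class/phylum-labelled metadata, noisy
  titrations and assay tables, all with ground truth for testing.

## Worked example

```python
import numpy as np
from dcache_ai2 import (FamilyGenConfig, OneSiteParams, ReferencePocketModel,
                        TitrationProtocol, build_column_map, compute_pfm,
                        fit_one_site, generate_family, injection_heats,
                        screen_family, simulate_titration, top_conserved)

ref = ReferencePocketModel()
cfg = FamilyGenConfig(n_seqs=2000, full_match_fraction=0.10, seed=7)
family, metadata, truth = generate_family(cfg)
cmap = build_column_map(family, ref)
result = screen_family(family, cmap, ref, k=5)
print(f"{result.n_passing} of {len(family)} domains carry the full RWYDD signature")

pfm = compute_pfm(family, cmap, region=(100, 175))
print("most conserved pocket positions:", sorted(top_conserved(pfm, 5)))

protocol = TitrationProtocol(syringe_conc_M=700e-6, cell_conc_M=70e-6)
truth_p = OneSiteParams(Kd=0.14e-6, n=1.0, dH=-40_000.0)
noise = 0.02 * np.max(np.abs(injection_heats(protocol, truth_p)))
thermogram = simulate_titration(protocol, truth_p, noise, seed=3)
fit = fit_one_site(thermogram, protocol)
print(f"fitted Kd = {fit.params.Kd * 1e6:.3f} uM  (truth 0.140), "
      f"n = {fit.params.n:.2f}, Wiseman c = {fit.wiseman_c:.0f}")
```

prints

```
201 of 2001 domains carry the full RWYDD signature
most conserved pocket positions: [126, 128, 144, 146, 173]
fitted Kd = 0.119 uM  (truth 0.140), n = 0.99, Wiseman c = 579
```

The screen finds exactly the 200 planted matches plus the reference row
itself; the conservation profile ranks the five signature positions on
top; and a single noisy titration at Wiseman c ≈ 500 recovers the
generating Kd to within the noise-limited uncertainty of one replicate
(medians over replicates do much better — see below).

The same analyses are available from the shell:

```sh
dcache-ai2 simulate-family --n-seqs 2000 --seed 7 --out-dir fam
dcache-ai2 scan --alignment fam/family.afa --table fam/metadata.tsv --k 5
dcache-ai2 itc-sim --kd 1.4e-7 --syringe 7e-4 --cell 7e-5 --noise 3 --seed 3
dcache-ai2 itc-fit thermogram.csv
dcache-ai2 assay ri 6.5 3.5
```

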