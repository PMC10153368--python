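# bpascreen

Virtual-screening toolkit for CNS-directed drug candidates built on the
benzoyl-phenoxy-acetamide (BPA) scaffold — the chemotype of fenofibrate and
of a series of pyridine-substituted amides ("HR" compounds) pursued as
glioblastoma therapeutics. Glioblastoma drugs fail mostly at the
blood–brain barrier (BBB), so the screen asks one integrated question per
structure: *is this molecule likely to reach a brain tumor at a toxic
concentration, without being cardiotoxic or insoluble?*

The package provides, as a plain Python library with a thin CLI:

- **Descriptors** (`bpascreen.descriptors`) — MW, TPSA, Lipinski HBD/HBA,
  aromatic rings, heavy atoms, Crippen ClogP; Henderson–Hasselbalch
  ClogD(pH); ESOL logS (Delaney 2004); Miller additive polarizability
  (Miller 1990); and the **minimal projection area** (MPA), the smallest
  van-der-Waals silhouette of the low-energy conformer over all projection
  directions, with a brute-force exact-geometry oracle for verification.
- **Brain-penetration scores** (`bpascreen.scoring`) — CNS-MPO
  (Wager 2010): sum of six piecewise-linear desirabilities of ClogP,
  ClogD(7.4), MW, TPSA, HBD, basic pKa, range 0–6; the BBB score
  (Gupta 2019): weighted five-component function of aromatic rings, heavy
  atoms, MWHBN = (HBD+HBA)/√MW, TPSA and pKa, also 0–6, with its
  coefficients stored as auditable JSON data; and logBB = log₁₀(brain:plasma).
- **Screening gate** (`bpascreen.screening`) — the candidate filter
  hERG < 5.5, −logS < 7.5, CNS-MPO > 3, BBB score ∈ [4, 5], MPA < 60 Å²,
  with calibration of thresholds from an acceptability-flagged reference
  panel, ranking, and a HOMO-energy nucleophilicity ordering.
- **Phase-I metabolism** (`bpascreen.metabolism`) — SMARTS-rule enumeration
  of hydrolysis / oxidation / reduction metabolites with formula-level mass
  balance, re-scored through the same descriptor stack.
- **Assay math** (`bpascreen.bioassay`) — MTT viability normalization,
  four-parameter logistic IC50 fitting, transwell permeability
  P = V_A·C_A/(t·S·C_L) with TEER normalization, and the tumor-exposure
  ratio.
- **Synthetic data** (`bpascreen.synthetic`) — seeded generators for every
  input above, so the whole pipeline is testable without external data.

External quantities the open stack does not predict (pKa, hERG pIC50,
frontier-orbital energies) enter as per-compound overrides and flow through
untouched.

## Worked example

```python
from bpascreen import builtin_fixture, full_descriptors, score_descriptors

hr67 = builtin_fixture("hr_named")["HR67"]   # the lead pyridin-3-yl amide
ds = full_descriptors(hr67)                  # includes the 3D MPA search
s = score_descriptors(ds)
print(f"MW {ds.mw:.1f}  TPSA {ds.tpsa:.1f}  ClogD {ds.clogd_74:.2f}  "
      f"MPA {ds.mpa:.1f}  CNS-MPO {s.cns_mpo:.2f}  BBB {s.bbb_score:.2f}")
```

prints

```
MW 394.9  TPSA 68.3  ClogD 4.76  MPA 49.0  CNS-MPO 3.70  BBB 3.93
```

i.e. HR67 is slightly large and lipophilic for a textbook CNS drug
(CNS-MPO 3.70, just under the conventional ≥ 4 band) but its silhouette is
compact (MPA 49.0 Å² < 60) and its BBB score sits at the edge of the
favorable [4, 5] band — exactly the "borderline but plausible
brain-penetrant" profile that motivates taking it forward. The
`examples/` directory holds one short narrative script per capability
(descriptors/scores, gate calibration, metabolites, IC50 fitting,
permeability); each prints the numbers it computes and what they mean, e.g.

```bash
python examples/04_ic50_fit.py
# true IC50 2.87 uM -> fitted 2.84 uM (hill 1.00, top 97.7, bottom 0.0, ...)
```

The same functionality is scriptable via the thin CLI:

```bash
bpascreen screen --panel hr_named --out screen_out   # end-to-end report bundle
bpascreen score controls --out scores.csv
bpascreen simulate dose-response --out sim/ && bpascreen ic50 sim/dose_response.csv --out fits.csv
```

`screen` writes `descriptors.csv`, `scores.csv`, `gate_report.csv`,
`shortlist.csv`, a JSON audit trail with every criterion, value and bound,
and a run log with the tool version and config hash; reruns with the same
seed are byte-identical.

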