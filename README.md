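# nadquant

Targeted, stable-isotope-dilution LC-MS/MS quantification of the NAD⁺
metabolome — from SRM chromatogram traces to intracellular molar
concentrations, with a ground-truthed synthetic-run generator for validating
every step.

## The problem

The NAD⁺ metabolome (NAD⁺, NADH, NADP, the mononucleotides NMN and NAMN, the
nucleosides NR and NAR, the bases Nam and NA, NAAD, ADPr, and reference
nucleotides such as ATP, ADP, UMP, CMP, IMP, uridine, cytidine and inosine)
spans ~1 µM to ~1 mM inside cells, and many species differ by a single
Dalton. A triple-quadrupole SRM assay resolves them across two porous
graphitic carbon separations — 16 metabolites in an alkaline run (32.2 min)
and Nam, NA, NR in an acidic run (23.4 min) — but raw peak areas are
unusable for absolute quantification because co-eluting matrix components
suppress ionization unpredictably.

The isotope-dilution answer: every sample is co-injected with heavy internal
standards — a uniformly ¹³C-glucose-grown yeast extract whose
carbohydrate-containing metabolites are shifted +5 Da per ribosyl moiety
(mononucleotides +5, dinucleotides +10), plus ¹⁸O-labeled Nam and NR spikes
for the acidic separation. A heavy isotopologue co-elutes exactly with its
light analyte and suffers the *same* suppression factor *s*, so with peak
areas `A` and response factor `R`,

    A_light = n_light · R · s,   A_heavy = n_heavy · R · s
    ⟹  n_light = (A_light / A_heavy) · n_heavy          (s and R cancel)

The heavy amounts `n_heavy` are assigned once, by running the heavy lot
mixed 1:1 with a 9-level standard series (0–200 µM pre-mix; 0.125–250 pmol
on column after the 1:1 mix and 2.5 µl injection). Two metabolites lack a
usable heavy channel and are quantified through a surrogate with a
response-factor correction `cf = R_target / R_surrogate`: IMP against the
heavy NMN peak, NA against the heavy Nam spike.

Finally, pmol on column becomes intracellular µM through the extraction
bookkeeping: a pellet resuspended at 100 µl per 3.6 mg dry mass, diluted to
OD₂₆₀ = 14, mixed 1:1 and injected at 2.5 µl means 1.25 µl of extract is
analyzed; the same fraction of the cells' total volume (cell count ×
per-cell volume; 70 fl for yeast, 2.5 pl for HeLa) is the effective volume
on column, and `µM = pmol / volume`. Example: 3×10⁷ yeast cells hold 2.1 µl
of cell water, 1.25 µl of a 100 µl resuspension is 1.25%, so 26 nl is
analyzed and 1 pmol on column ≈ 38 µM.

## Worked example

Simulate a full run set (9-level standard series in both separations plus
triplicate dishes of a cultured cell line) and quantify it:

```
$ nadquant simulate --out demo --seed 1 --replicates 3 --no-qc
wrote 24 injections to demo
$ nadquant quantify demo --out demo_q
...
flag: S1_r3_acidic/NA: below LOQ (<3.31 uM)
quantified 3 sample(s) -> demo_q
```

`demo_q/report_S1_r1.csv` then reads (abridged):

```
metabolite reported           flag
   Uridine      210             ok
       CMP      170             ok
       NMN     <1.8      below_loq
       IMP       89 via_correction
       ATP     1100             ok
       NAD      260             ok
      NADH        7             ok
      NADP       53             ok
       Nam       38             ok
        NA     <3.3      below_loq
  NAD/NADH       37          ratio
  NAD/NADP      4.8          ratio
```

Concentrations are intracellular µM at two significant figures. Metabolites
whose light peak never reaches signal-to-noise 10 — or whose amount falls
below the limit of quantification (the amount producing S/N = 10 on the
standard series) — are reported as an upper bound (`<3.3`), converted
through the same volume bookkeeping as real measurements. `via_correction`
marks surrogate-quantified analytes. AMP is never reported (indistinguishable
from on-source ATP/ADP fragmentation) and NADPH is monitored but excluded
(not reliably preserved); NADP carries a caveat that it may include oxidized
NADPH. The generating truth for this demo run had uridine at 210 µM, NAD⁺ at
260 µM and an NAD⁺:NADH ratio of 39 — the report recovers them within the
simulated run-to-run noise.

`nadquant qc` writes the robustness table: per-metabolite capacity factor
k′ = (RT − t₀)/t₀, R², LOQ, method RSD (six independently prepared 10 µM
standard solutions) and system RSD (four injections of one solution).

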