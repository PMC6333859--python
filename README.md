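# epikinet

Dynamic FDG-PET kinetic modelling and asymmetry-index analysis for
epileptic-focus lateralization.

## The problem

Interictal FDG-PET localizes epileptic foci through their hypometabolism,
conventionally read from a single late static scan.  A dynamic scan
acquired from injection onward lets one fit a compartment model and
separate the steps of glucose uptake: capillary influx/efflux (K1, k2)
from hexokinase phosphorylation (k3).  Comparing each candidate focus with
its mirror-hemisphere homolog via a side-to-side asymmetry index makes the
analysis independent of the global calibration of the input function — so
a bloodless, image-derived input function (IDIF) from the carotid arteries
suffices.  `epikinet` implements this whole analysis for VOI-level data,
together with a fully controlled synthetic-cohort generator, so every
stage can be validated without patient data.

## The model

Irreversible two-tissue compartment model (k4 = 0) with plasma input Cp:

    dC1/dt = K1·Cp − (k2 + k3)·C1        (free FDG)
    dC2/dt = k3·C1                        (trapped FDG-6-P)
    Cmodel = (1 − vB)·(C1 + C2) + vB·Cp

with the derived net metabolic flux **Ki = K1·k3/(k2 + k3)**.
The carotid measurement follows the partial-volume mixing model

    Cmeas(t) = RC·Cinput(t) + SP·Cbkgd(t)

with the recovery coefficient RC and spill-in factor SP estimated from a
cylinder phantom blurred at the scanner resolution.  The asymmetry index of
any quantity q is

    ASYM = (q_contra − q_ipsi) · 2 / (q_contra + q_ipsi)

positive when the focus side is hypometabolic, bounded in [−2, 2], and
invariant under any common rescaling of both sides.  Group-level inference
uses Wilcoxon rank tests (exact enumeration at small n) and Spearman rank
correlations.

## Worked example

`examples/fit_single_subject.py` simulates a 39-frame, 60-minute dynamic
scan with a Feng bolus input, generates a noiseless hippocampal TAC from
known parameters and fits it back:

```
               truth      fitted
K1            0.1020    0.102000
k2            0.1300    0.130000
k3            0.0620    0.062000
Ki            0.0329    0.032937
converged: True, WRSS: 1.937e-23
```

The fit recovers the micro-parameters essentially exactly; `Ki` is the
derived trapping flux in mL·min⁻¹·mL⁻¹.  The other examples cover the
IDIF partial-volume correction (`idif_partial_volume.py`, which prints
RC = 0.556, SP = 0.444 for a 6 mm vessel at 5.4 mm FWHM and shows the
mix→correct round trip is exact), atlas-based VOI extraction
(`region_extraction.py`) and a small end-to-end cohort study
(`cohort_asymmetry_study.py`), where six synthetic patients carrying
injected micro-parameter asymmetries of 0.12/0.14/0.21 yield cohort-mean
measured ASYMs of 0.117/0.135/0.210 against control absolute ASYMs of
0.01–0.03, with rank-sum p < 0.02 for every parameter.

A shell front end mirrors the library:

```sh
epikinet simulate -c cohort.yaml -o data/          # synthetic cohort
epikinet run -c run.yaml -o run_dir/ --seed 1      # full pipeline + report
```

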