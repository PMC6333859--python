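"""A small synthetic asymmetry study, end to end.

Simulates patients carrying a hypometabolic focus (micro-parameter
asymmetries injected at the reported cohort means) and symmetric controls,
runs IDIF correction, kinetic fitting and the asymmetry statistics, and
prints the cohort-level summary.  Patients' epileptogenic ASYM should sit
near the injected means while controls' absolute ASYM stays near zero.
"""

from epikinet.pipeline import (
    build_asym_table,
    cohort_statistics,
    fit_cohort,
    _region_class_table,
    _static_table,
)
from epikinet.synthetic_cohort import CohortSpec, simulate_cohort

spec = CohortSpec(n_patients=6, n_controls=4, asym_sd=0.02, noise_cv=0.03,
                  include_reference_regions=False, seed=11)
cohort = simulate_cohort(spec)
fits = fit_cohort(cohort, spec.pvc())
asym = build_asym_table(fits, _static_table(cohort), _region_class_table(cohort))
stats = cohort_statistics(asym)

print("cohort-mean ASYM (signed for patients, mean |ASYM| for controls):")
print(stats.cohort_means.to_string(index=False))
print()
print("patients vs controls (Wilcoxon rank-sum):")
print(stats.group_tests.to_string(index=False))
print()
print("injected micro-parameter means were K1 0.12, k2 0.14, k3 0.21;")
print("Ki and static-AC asymmetry emerge from the kinetics.")
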