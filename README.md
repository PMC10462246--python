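# predose

Organ-level preclinical radiopharmaceutical dosimetry in Python: from
animal biodistribution measurements to absorbed, equivalent, effective and
RBE-weighted dose coefficients, following the MIRD schema.

The package is for radiopharmaceutical scientists who have (or plan)
biodistribution data — per-animal activity concentrations in %IA/g or SUV —
and need organ dose estimates on a computational phantom, either for the
same species (small-animal dosimetry) or extrapolated to a human reference
phantom (translational dosimetry). It covers the full chain the dosimetry
protocol prescribes; the phantom masses and S-value tables themselves are
user-supplied delimited-text exports from established dosimetry software.

## The model

The absorbed dose coefficient of a target region rT is

    d(rT) = Σ_rS  ã(rS) · S(rT ← rS)        [Gy/Bq]

where S(rT ← rS) [Gy/(Bq·s)] is the absorbed dose rate in rT per unit
activity in rS, and ã(rS) [h] is the time-integrated activity coefficient
(TIAC): the integral over all time of the decay-uncorrected fraction of
administered activity in rS. The pipeline estimates ã by:

1. converting measurements to SUV (SUV = %IA/g · M_body/100) and averaging
   replicates per time point;
2. transposing SUV onto phantom source regions under the assumption that
   SUV is species- and size-invariant:
   a(rS, t) = SUV(rS, t) · M(rS)/M(TB) · e^(−λp·t), masses from the phantom;
3. integrating by trapezoids (with conservative head/tail closures) or by
   fitting a(t) = Σψ cψ·e^(−(λbψ+λp)·t) and evaluating
   ã = Σψ cψ/(λbψ+λp) exactly;
4. routing urinary excretion through a voiding-bladder model and closing
   the balance with a rest-of-body term.

Equivalent dose (wR), sex-averaged effective dose (wT; reference humans
only) and RBE-weighted dose for deterministic endpoints are computed on
top. Details, assumptions and numerical choices: `docs/methods.md`.

## Worked example

A synthetic mouse study with known kinetics, pushed through the whole
pipeline (the `predose.synthetic` module generates test data for any study
design; with real data you would load `biodist.csv` instead):

```python
import warnings
from predose import *

nuclide = Radionuclide("Lu177like", half_life_h=159.4, delta_np_J=2.36e-14)
schedule = plan_empirical(8, 20.0)          # 8 points for a 20 h effective half-life
print("schedule:", schedule)

phantom = load_phantom("tests/data/phantom_mouse.csv")
spec = KineticSpec(                          # ground-truth kinetics: (amplitude, lambda_b)
    regions={
        "Liver":   ((0.25, 0.08), (0.05, 0.008)),
        "Kidneys": ((0.10, 0.15),),
        "Carcass": ((0.45, 0.08), (0.15, 0.008)),
    },
    half_life_h=159.4, times_h=tuple(schedule.times_h), seed=42,
)
sim = simulate_biodist(spec, phantom)        # 3 animals x 8 time points, 5% CV
series = aggregate_by_region(measurements_from_frame(sim.biodist))

tiacs = []
for region in spec.regions:
    tac = transpose_region(series[region], phantom, nuclide)
    fit = fit_exponentials(tac, nuclide, n_components="auto")
    tiacs.append(tiac_from_fit(fit))
    print(f"TIAC {region}: {tiacs[-1].tiac_h:.3f} h "
          f"({fit.n_components} comp, truth {spec.true_tiac(region):.3f} h)")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")          # sparse toy matrix: absent pairs are S = 0
    svalues = load_svalues("tests/data/svalues_mouse.csv", phantom, "Lu177like")
report = absorbed_dose(tiacs, svalues, phantom=phantom)
for target in report.targets:
    print(f"d({target}) = {report.absorbed_Gy_per_Bq[target]:.3e} Gy/Bq")

check = self_dose_check(tiacs[0], phantom.mass("Liver"), nuclide,
                        report.absorbed_Gy_per_Bq["Liver"])
print("self-dose check Liver: ratio %.2f" % check["ratio"])
```

Output:

```
schedule: empirical schedule (Te = 20 h): 2.86, 8.59, 19.1, 32.7, 48.7, 67, 87.2, 109 h
TIAC Liver: 7.130 h (2 comp, truth 7.013 h)
TIAC Kidneys: 0.641 h (1 comp, truth 0.648 h)
TIAC Carcass: 17.262 h (2 comp, truth 17.482 h)
d(Kidneys) = 1.211e-07 Gy/Bq
d(Liver) = 3.348e-07 Gy/Bq
d(Redmarrow) = 2.149e-08 Gy/Bq
d(Urinarybladdercontents) = 0.000e+00 Gy/Bq
self-dose check Liver: ratio 0.95
```

Reading the numbers: at 5% measurement noise with 3 animals per time point,
the fitted TIACs land within ~2% of the ground truth; the model selector
identifies the bi-exponential liver/carcass clearance and the
mono-exponential kidney washout. The liver receives 3.3·10⁻⁷ Gy per Bq
administered, and the quick local-absorption estimate (ã·Δnp/M) agrees with
the full S-value computation to within 5% — the sanity check one should
always run. The bladder dose is zero here because no urinary fractions were
routed; see `tiac_bladder` for the voiding model.

The same steps are scriptable from the shell:

```sh
predose plan --n 8 --te-h 20
predose simulate --spec spec.yaml --phantom phantom.csv --seed 42 --out sim/
predose fit --input tac.csv --nuclide-half-life-h 159.4 --method exp --components auto
predose dose --tiac tiac.csv --phantom phantom.csv --svalues svalues.csv --weights weights.csv
```

## File formats

Comma-delimited UTF-8, one header row, `#` comments. Masses in grams,
half-lives in hours, S-values in Gy/(Bq·s):

| file | columns |
|---|---|
| `phantom.csv` | `region, mass_g, is_source, is_target[, species]` + one `TOTALBODY` row |
| `svalues.csv` | `target, source, svalue_Gy_per_Bq_s[, radiation_type]` |
| `nuclide.csv` | `name, half_life_h, delta_np_J, radiation_type, dose_fraction` |
| `weights.csv` | `kind (wT\|wR), key, value` |
| `biodist.csv` | `region, time_h, replicate, value, unit, body_mass_g` |
| `region_map.csv` | `measured_region, phantom_region` |

The phantoms and S-value matrices under `tests/data/` are synthetic toys
for testing only — not reference phantoms or published S-value libraries.

## Scope

No Monte Carlo transport, S-value or phantom generation, voxel dosimetry,
image quantification, compartmental modeling, or radioactive progeny —
S-values and phantom masses are inputs, exported from dedicated dosimetry
software.
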