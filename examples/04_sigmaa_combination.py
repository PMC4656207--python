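"""sigma-A weighting and von Mises phase combination.

Estimates sigma-A between observed and model amplitudes, converts it into
per-reflection figures of merit, and combines two phase sources with the
weights those figures imply.
"""

import numpy as np

import phaseloop as pl
from phaseloop.sigmaa import normalize_amplitudes

bundle = pl.standard_scenario(seed=1, n_residues=30,
                              cell=pl.UnitCell(46, 48, 50), d_min=2.8,
                              em_resolution=5.5, n_extension_steps=3)

# a deliberately incomplete model: 40% of the true atoms
rng = np.random.default_rng(0)
keep = rng.permutation(len(bundle.truth_model))[: int(0.4 * len(bundle.truth_model))]
partial = bundle.truth_model.select(np.sort(keep))
model_phases = pl.phases_from_built_model(partial, bundle.obs, bundle.cell,
                                          bundle.sym)

e_obs = normalize_amplitudes(bundle.obs, 10)
e_calc = normalize_amplitudes(
    pl.structure_factors_from_model(partial, bundle.cell, d_min=2.8), 10)
sigA = pl.estimate_sigma_a(e_obs, e_calc, 10)
print("sigma-A per shell (low -> high resolution):")
for dmx, dmn, v in zip(sigA.d_max, sigA.d_min, sigA.value):
    print(f"  {min(dmx, 99.0):5.1f} - {dmn:4.2f} A : {v:.3f}")
print(f"mean FOM of the 40% model phases: {model_phases.fom.mean():.3f}")

# combine with an independent, better phase source (truth + 30 deg noise)
other = bundle.truth_phases.copy()
other.phi = (other.phi + rng.normal(scale=30.0, size=len(other))) % 360
other.fom = np.full(len(other), float(np.exp(-0.5 * np.radians(30) ** 2)))

combined = pl.combine_phases(other, model_phases)
for label, src in (("model alone", model_phases), ("EM-like alone", other),
                   ("combined", combined)):
    w = pl.weighted_mean_phase_error(src, bundle.truth_phases)
    print(f"{label:14s} wMPE {w:5.1f} deg")
# sigma-A measures how much the model amplitudes know about the data;
# the resulting concentrations weight each source's phase vector, and the
# combination is at least as informative as the better source.
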