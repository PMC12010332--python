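"""Run configuration and end-to-end synthetic pipeline orchestration.

The pipeline wires every stage together on synthetic inputs with known
truth: Gaussian ensemble -> Schlitter entropy; harmonic chain -> normal-mode
thermochemistry and the classical-limit cross-check; freely rotating chains
-> persistence length; Langevin trace -> PMF and autocorrelation; harmonic
alchemical dataset -> TI/MBAR and the thermodynamic cycle; reference tables
-> ledger totals and per-residue slopes.  Given a configuration (which is
hashed into every output) the numeric results are byte-identical across
reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .errors import ConfigError
from . import alchemy, ledger, metrics, nma, schlitter, synthetic

_FIELD_TYPES = {
    "temperature": float,
    "bin_width": float,
    "equilibration_discard_ps": float,
    "stride": int,
    "seed": int,
    "residue_count_policy": str,
    "output_dir": str,
}


@dataclass
class RunConfig:
    """Flat, typed run configuration; serialized verbatim into every output."""

    temperature: float = 300.0
    bin_width: float = 0.05
    equilibration_discard_ps: float = 0.0
    stride: int = 1
    seed: int = 0
    residue_count_policy: str = "repeat_residues_excluding_caps"
    output_dir: str = "linkerthermo_out"

    def __post_init__(self):
        if self.temperature <= 0:
            raise ConfigError("temperature must be positive")
        if self.bin_width <= 0:
            raise ConfigError("bin_width must be positive")
        if self.stride < 1:
            raise ConfigError("stride must be >= 1")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse ``key = value`` lines; unknown keys are errors."""
        values = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
                key, raw = (s.strip() for s in line.split("=", 1))
                if key not in _FIELD_TYPES:
                    raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
                try:
                    values[key] = _FIELD_TYPES[key](raw)
                except ValueError as exc:
                    raise ConfigError(f"{path}:{lineno}: bad value for {key}: {raw!r}") from exc
        return cls(**values)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig, manifest: dict | None = None) -> dict:
    """Run the all-synthetic demo pipeline and write its reports.

    ``manifest`` may map stage names to input files (a missing file is a
    clean error); with no manifest every stage generates its own synthetic
    input from the config seed.  Writes ``results.json`` (numeric outputs,
    deterministic) and ``runlog.json`` (stage log incl. wall times) into
    ``config.output_dir`` and returns the results dict.
    """
    if manifest:
        for stage, path in manifest.items():
            if not Path(path).exists():
                raise ConfigError(f"manifest entry {stage!r}: file {path} not found")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    t = config.temperature
    seed = config.seed
    results: dict = {"config": config.as_dict(), "config_hash": config.config_hash(),
                     "version": __version__}
    log: list[dict] = []

    def stage(name):
        log.append({"stage": name, "t_wall": time.time()})

    # 1. Schlitter on a Gaussian ensemble with known covariance
    stage("schlitter")
    rng = np.random.default_rng(seed)
    n_atoms = 3
    A = rng.standard_normal((3 * n_atoms, 3 * n_atoms)) * 0.03
    cov = A @ A.T + 0.02 ** 2 * np.eye(3 * n_atoms)
    ens = synthetic.gaussian_ensemble(cov, masses=12.0, n_frames=20_000,
                                      seed=seed + 1, temperature=t)
    cm = schlitter.build_covariance(ens.frames, start_time_ps=0.0,
                                    stride=config.stride)
    rep = schlitter.schlitter_entropy(cm, temperature=t, remove_rigid_modes=0)
    results["schlitter"] = {
        "minus_TS_estimate_kJ_mol": rep.minus_TS_schlitter,
        "minus_TS_truth_kJ_mol": ens.truth["minus_TS_schlitter"],
        "n_frames": ens.frames.n_frames,
    }

    # 2. harmonic chain: RRHO vs classical-limit Schlitter
    stage("nma_rrho")
    chain = synthetic.harmonic_chain(n_beads=6, force_constant=30.0, mass=12.0,
                                     temperature=t, n_frames=20_000, seed=seed + 2)
    modes = nma.mass_weight_and_diagonalize(chain.hessian)
    rrho = nma.rrho_thermochemistry(modes, chain.hessian.topology,
                                    chain.hessian.reference_coordinates, t)
    cm2 = schlitter.build_covariance(chain.frames, start_time_ps=0.0)
    rep2 = schlitter.schlitter_entropy(cm2, temperature=t, remove_rigid_modes=0)
    results["rrho"] = rrho.as_dict()
    results["cross_check"] = {
        "minus_TS_schlitter_sampled": rep2.minus_TS_schlitter,
        "minus_TS_vib_rrho": rrho.minus_TS_vib,
        "max_beta_hbar_omega": chain.truth["max_beta_hbar_omega"],
    }

    # 3. persistence length on freely rotating chains
    stage("persistence")
    frc = synthetic.frc_chain(n_bonds=50, bond_length=0.38, cos_theta=0.8,
                              n_chains=2000, seed=seed + 3)
    fit = metrics.persistence_length(frc.frames, np.arange(51))
    results["persistence"] = {"l_p_nm": fit.l_p, "truth_nm": frc.truth["l_p"],
                              "r_squared": fit.r_squared}

    # 4. PMF + autocorrelation from a Langevin trace
    stage("pmf")
    lng = synthetic.langevin_cv("harmonic", {"k": 100.0}, n_steps=200_000,
                                dt=0.01, friction=5.0, temperature=t,
                                seed=seed + 4)
    fes = metrics.fes_from_cv(lng.cv, bin_width=config.bin_width, temperature=t)
    acf = metrics.autocorrelation(lng.cv, max_lag=1000)
    fes.write(outdir / "fes.txt")
    results["pmf"] = {"n_occupied_bins": int((fes.counts > 0).sum()),
                      "sample_variance_nm2": float(lng.cv.values.var()),
                      "truth_variance_nm2": lng.truth["variance"],
                      "tau_int_frames": acf.tau_int}

    # 5. alchemy: TI vs MBAR on the harmonic toy + cycle
    stage("alchemy")
    alc = synthetic.harmonic_alchemy(1000.0, 4000.0, n_states=5,
                                     samples_per_state=2000, temperature=t,
                                     seed=seed + 5)
    ti = alchemy.ti_integrate(alc.dataset)
    mbar = alchemy.mbar_solve(alc.dataset)
    check = alchemy.consistency_check(ti, mbar)
    vac = synthetic.harmonic_alchemy(1000.0, 2000.0, n_states=5,
                                     samples_per_state=2000, temperature=t,
                                     seed=seed + 6)
    cyc = alchemy.solvation_cycle(mbar, alchemy.mbar_solve(vac.dataset))
    results["alchemy"] = {
        "delta_A_TI_kJ_mol": ti.delta_A, "delta_A_MBAR_kJ_mol": mbar.delta_A,
        "delta_A_truth_kJ_mol": alc.truth["delta_A"],
        "consistency_pass": check.passed,
        "cycle_delta_A_kJ_mol": cyc.delta_A,
    }

    # 6. ledger on the shipped reference tables
    stage("ledger")
    comps = ledger.reference_components("charmm36m", temperature=t)
    entries = [ledger.assemble_ledger(c) for c in comps]
    zpve_slope = ledger.fit_slopes([c for c in comps if c.linker_id.endswith("P")
                                    or "(AP)" in c.linker_id], "zpve")
    results["ledger"] = {
        "totals_kJ_mol": {e.linker_id: e.total for e in entries},
        "all_positive": all(e.total is not None and e.total > 0 for e in entries),
        "zpve_slope_AP_kJ_mol_per_residue": zpve_slope.slope,
    }

    results_path = outdir / "results.json"
    results_path.write_text(json.dumps(results, indent=2, sort_keys=True,
                                       default=_json_default) + "\n")
    (outdir / "runlog.json").write_text(json.dumps(
        {"stages": log, "config_hash": config.config_hash(),
         "version": __version__}, indent=2) + "\n")
    return results


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
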