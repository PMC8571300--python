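"""End-to-end orchestration: titration runs, artifact output and
ground-truth recovery reports.

A run takes a :class:`RunConfig`, simulates (or loads) traces for each
Mg2+ condition, fits the folding-kinetics model per condition, performs
the cross-condition Hill analysis and critical-Mg2+ determination, and
writes every artifact plus a single JSON manifest under the output
directory (layout: ``traces/``, ``idealized/``, ``kinetics/``,
``figures/``, ``manifest.json``).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from . import kinetics as _kinetics
from . import synth as _synth
from .models import FoldingKinetics

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_titration_analysis", "validate_against_truth"]


@dataclass
class RunConfig:
    """Configuration of an end-to-end titration run."""

    mode: str = "synthetic"  # synthetic | traces
    mg_concs: tuple = (0.01, 0.1, 1.0, 10.0, 100.0)
    n_traces: int = 50
    duration: float = 30.0
    frame_interval: float = 0.025
    n_states: int = 3
    temperature: float = 298.15
    seed: int | None = None
    output_dir: str = "xrfret_run"
    trace_files: dict = field(default_factory=dict)  # mg -> TSV path
    emission: dict = field(default_factory=dict)
    save_figures: bool = False

    def validate(self) -> None:
        if self.mode not in ("synthetic", "traces"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.mode == "synthetic" and self.n_traces < 1:
            raise ValueError("n_traces must be >= 1 for synthetic runs")
        if self.mode == "traces" and not self.trace_files:
            raise ValueError("mode='traces' requires trace_files")
        if len(self.mg_concs) == 0:
            raise ValueError("at least one Mg2+ condition is required")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        known = {k: v for k, v in payload.items() if k in cls.__dataclass_fields__}
        unknown = set(payload) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        if "mg_concs" in known:
            cfg.mg_concs = tuple(cfg.mg_concs)
        cfg.validate()
        return cfg


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    return obj


def run_titration_analysis(config: RunConfig, outdir=None) -> dict:
    """Run the full titration analysis and return the manifest.

    The manifest links every artifact and carries the per-condition
    numeric summaries (state means, populations, rates, free energies)
    plus the cross-condition Hill fits and critical Mg2+; identical
    configs and seeds produce identical manifests.
    """
    config.validate()
    outdir = Path(outdir or config.output_dir)
    for sub in ("traces", "idealized", "kinetics", "figures"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    master = np.random.SeedSequence(config.seed)
    cond_seeds = master.spawn(len(config.mg_concs) + 1)
    manifest = {"config": _round_floats(vars(config).copy()), "conditions": [], "artifacts": {}}
    truth = {}
    per_state_fractions = {"L": [], "I": [], "H": []}
    concs = []

    for ci, mg in enumerate(config.mg_concs):
        t0 = time.time()
        label = f"mg_{mg:g}"
        try:
            if config.mode == "synthetic":
                emission = _synth.EmissionModel(**config.emission)
                ds = _synth.simulate_titration(
                    _synth.MgRateLaw.default(),
                    [mg],
                    n_traces=config.n_traces,
                    duration=config.duration,
                    emission=emission,
                    frame_interval=config.frame_interval,
                    seed=cond_seeds[ci],
                )
                cond = ds.conditions[0]
                traces = cond.traces
                truth[mg] = cond.truth_rates
                trace_path = outdir / "traces" / f"{label}.tsv"
                _io.write_traces_tsv(
                    traces, trace_path,
                    params={"mg_mM": mg, **cond.truth_rates.as_dict()},
                    seed=config.seed,
                )
            else:
                trace_path = Path(config.trace_files[mg])
                traces = _io.read_traces_tsv(trace_path)

            model = FoldingKinetics(
                traces, n_states=config.n_states, temperature=config.temperature
            )
            res = model.fit(
                seed=int(cond_seeds[ci].generate_state(1)[0] % (2**31 - 1)),
                condition=mg,
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'condition analysis' failed at {label}: {exc}") from exc

        ideal_path = outdir / "idealized" / f"{label}.tsv"
        rows = []
        for tr in res.idealized:
            rows.append(
                pd.DataFrame(
                    {"trace_id": tr.trace_id, "frame": np.arange(len(tr.fret)),
                     "E": tr.fret, "state": tr.states}
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(ideal_path, sep="\t", index=False)

        kin_dir = outdir / "kinetics"
        rates_path = kin_dir / f"{label}_rates.csv"
        res.rates_frame().to_csv(rates_path, index=False)
        tdp_path = kin_dir / f"{label}_tdp.csv"
        np.savetxt(tdp_path, res.tdp.density, delimiter=",")
        hist_path = kin_dir / f"{label}_histogram.csv"
        pd.DataFrame(
            {"center": res.histogram.centers, "probability": res.histogram.frequencies}
        ).to_csv(hist_path, index=False)

        landscape = None
        if res.landscape is not None:
            landscape = {
                "dG_kcal_mol": res.landscape.dg.tolist(),
                "barriers_kcal_mol": res.landscape.barriers,
                "closure_residual": res.landscape.closure_residual,
                "temperature_K": res.landscape.temperature,
            }
            (kin_dir / f"{label}_landscape.json").write_text(
                json.dumps(_round_floats(landscape), indent=2)
            )

        if config.save_figures:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, axes = plt.subplots(1, 2, figsize=(8, 3.2))
            res.plot_histogram(axes[0])
            res.plot_tdp(axes[1])
            fig.suptitle(f"Mg2+ = {mg:g} mM")
            fig.tight_layout()
            fig.savefig(outdir / "figures" / f"{label}.png", dpi=120)
            plt.close(fig)

        concs.append(mg)
        for i, lbl in enumerate(("L", "I", "H")):
            per_state_fractions[lbl].append(float(res.occupancy[i]))
        manifest["conditions"].append(
            _round_floats(
                {
                    "mg_mM": mg,
                    "n_traces": len(traces),
                    "state_means": res.hmm.means,
                    "state_sds": res.hmm.sds,
                    "occupancy": res.occupancy,
                    "mixture_fractions": (
                        res.populations.fractions if res.populations else None
                    ),
                    "lifetimes_s": res.lifetimes.tau,
                    "rates_per_s": res.rates.as_dict(),
                    "transition_counts": res.counts.as_dict(),
                    "landscape": landscape,
                    "flags": res.rates.flags,
                    "elapsed_s": round(time.time() - t0, 2),
                }
            )
        )
        manifest["artifacts"][label] = {
            "traces": str(trace_path),
            "idealized": str(ideal_path),
            "rates": str(rates_path),
            "tdp": str(tdp_path),
            "histogram": str(hist_path),
        }
        log.info("condition %s done in %.1f s", label, time.time() - t0)

    # cross-condition titration analysis
    if len(concs) >= 4:
        try:
            hill_h = _kinetics.fit_hill(concs, per_state_fractions["H"], state="H")
            hill_l = _kinetics.fit_hill(concs, per_state_fractions["L"], state="L")
            crit = _kinetics.critical_mg(
                hill_h, hill_l, mg_range=(min(concs), max(concs))
            )
            manifest["titration"] = _round_floats(
                {
                    "hill_H": vars(hill_h) | {"se": hill_h.se},
                    "hill_L": vars(hill_l) | {"se": hill_l.se},
                    "critical_mg_mM": crit.value,
                    "critical_mg_flag": crit.flag,
                }
            )
        except (RuntimeError, ValueError) as exc:
            raise RuntimeError(f"stage 'Hill analysis' failed: {exc}") from exc

    if truth:
        manifest["truth_rates"] = _round_floats(
            {f"{mg:g}": r.as_dict() for mg, r in truth.items()}
        )

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def validate_against_truth(manifest: dict, truth=None) -> pd.DataFrame:
    """Tabulate relative recovery errors against generator ground truth.

    ``truth`` maps condition label (mg in mM) to a
    :class:`~xrfret.synth.GeneratorRates` (or a rate dict); for
    synthetic-mode manifests it defaults to the recorded truth.  Raises
    when condition labels do not match.
    """
    if truth is None:
        if "truth_rates" not in manifest:
            raise ValueError("manifest carries no ground truth; pass `truth`")
        truth = manifest["truth_rates"]
    truth = {
        float(k): (v.as_dict() if hasattr(v, "as_dict") else dict(v))
        for k, v in truth.items()
    }
    rows = []
    for cond in manifest["conditions"]:
        mg = float(cond["mg_mM"])
        if mg not in truth:
            raise ValueError(f"condition {mg} mM missing from ground truth")
        true_rates = truth[mg]
        est = cond["rates_per_s"]
        for name, kt in true_rates.items():
            ke = est[name]
            rel = (ke - kt) / kt if kt > 0 else np.nan
            rows.append(
                {"mg_mM": mg, "parameter": name, "truth": kt,
                 "estimate": ke, "relative_error": rel}
            )
        means = cond["state_means"]
        for lbl, m_est, m_true in zip(("L", "I", "H"), means, (0.3, 0.5, 0.9)):
            rows.append(
                {"mg_mM": mg, "parameter": f"E_{lbl}", "truth": m_true,
                 "estimate": m_est, "relative_error": (m_est - m_true) / m_true}
            )
    return pd.DataFrame(rows)
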