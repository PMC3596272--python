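"""End-to-end demo pipeline: simulate -> weights -> dating -> founder -> IBD.

Runs every analysis stage of the package on one synthetic scenario and
reports each estimate next to its configured truth, with a manifest recording
the config snapshot, seed, per-stage runtimes and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .data import allele_frequencies
from .founder import (allele_sharing_autocorrelation, autozygosity_summary,
                      detect_roh, fit_founder_date)
from .fstats import f4_ratio_ancestry
from .ibd import detect_ibd_segments, sharing_matrix
from .rolloff import (fit_single_exponential, fit_two_pulse, jackknife_date,
                      weighted_ld_curve)
from .simulate import (ScenarioConfig, simulate_admixture_graph,
                       simulate_scenario)
from .weights import freq_difference_weights, pca_loadings

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config_text: str
    seed: int
    version: str
    stages: list[dict] = field(default_factory=list)

    def record(self, name: str, runtime: float, payload) -> None:
        digest = hashlib.sha1(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()
        self.stages.append({"stage": name, "runtime_s": round(runtime, 3),
                            "sha1": digest})


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


def _total_pool_a(config: ScenarioConfig) -> float:
    # older pulse sets the mix; each later pulse replaces a fraction with A
    frac = config.pulses[0][1]
    for _, beta in config.pulses[1:]:
        frac = beta + (1 - beta) * frac
    return frac


def run_demo_pipeline(config: ScenarioConfig,
                      outdir: str | Path | None = None) -> dict:
    """Run all stages on one scenario; return the report as a plain dict."""
    report: dict = {"truth": {
        "pulses": [list(p) for p in config.pulses],
        "pool_a_fraction": _total_pool_a(config),
        "founder_event": list(config.founder_event) if config.founder_event else None,
    }}
    manifest = RunManifest("\n".join(
        f"{k}={v}" for k, v in vars(config).items()), config.seed, __version__)

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
            raise StageError(f"[{name}] {exc}") from exc
        dt = time.perf_counter() - t0
        logger.info("stage %-10s %6.1fs", name, dt)
        return out, dt

    sim, dt = stage("simulate", lambda: simulate_scenario(config))
    manifest.record("simulate", dt,
                    hashlib.sha1(sim.genotypes.dosages.tobytes()).hexdigest())

    def _weights():
        freqs = allele_frequencies(sim.genotypes, ["REFA", "REFB"])
        fd = freq_difference_weights(freqs, "REFA", "REFB")
        panel = sim.genotypes.take_samples(sim.genotypes.samples_in(["REFA", "REFB"]))
        pca = pca_loadings(panel)
        return fd, pca
    (fd_weights, pca_weights_), dt = stage("weights", _weights)
    manifest.record("weights", dt, float(fd_weights.values.sum()))

    def _ancestry():
        graph = simulate_admixture_graph(
            n_snps=min(config.n_snps, 50_000),
            alpha=report["truth"]["pool_a_fraction"],
            t_admix=config.pulses[0][0], seed=config.seed + 1)
        freqs = allele_frequencies(graph)
        est = f4_ratio_ancestry(freqs, "X", "OUT", "REF", "W", "S")
        return {"proportion": est.estimate, "se": est.std_err,
                "n_blocks": est.n_blocks}
    report["ancestry"], dt = stage("ancestry", _ancestry)
    manifest.record("ancestry", dt, report["ancestry"])

    def _dating():
        curve = weighted_ld_curve(sim.genotypes, fd_weights, pop="ADMIX")
        fit = fit_single_exponential(curve)
        jk = jackknife_date(sim.genotypes, fd_weights, pop="ADMIX")
        out = {"date_gen": fit.n_generations, "se_gen": jk.std_err,
               "amplitude": fit.amplitude, "affine": fit.affine}
        if len(config.pulses) > 1:
            tp = fit_two_pulse(curve)
            out["two_pulse"] = {"n1": tp.n1, "n2": tp.n2,
                                "degenerate": tp.degenerate}
        return out
    report["dating"], dt = stage("dating", _dating)
    manifest.record("dating", dt, report["dating"])

    def _founder():
        curve = allele_sharing_autocorrelation(sim.genotypes, "ADMIX", "ADMIXREF")
        fit = fit_founder_date(curve)
        return {"event_detected": bool(fit.event_detected),
                "date_gen": fit.t_generations if fit.event_detected else None}
    report["founder"], dt = stage("founder", _founder)
    manifest.record("founder", dt, report["founder"])

    def _roh():
        segs = detect_roh(sim.genotypes.take_samples(
            sim.genotypes.samples_in(["ADMIX", "ADMIXREF"])))
        summ = autozygosity_summary(segs, sim.genotypes.sample_ids[
            sim.genotypes.samples_in(["ADMIX", "ADMIXREF"])])
        target = summ[summ.index.str.startswith("ADMIX_")]
        control = summ[summ.index.str.startswith("ADMIXREF_")]
        return {"target_mean_mb": float(target["total_mb"].mean()),
                "control_mean_mb": float(control["total_mb"].mean()),
                "n_segments": int(summ["n_segments"].sum())}
    report["roh"], dt = stage("roh", _roh)
    manifest.record("roh", dt, report["roh"])

    def _ibd():
        segs = detect_ibd_segments(sim.haps)
        sm = sharing_matrix(segs, sim.haps.sample_ids, sim.haps.pop_labels)
        return {"pops": sm.pops, "matrix": sm.values.tolist(),
                "n_segments": len(segs)}
    report["ibd"], dt = stage("ibd", _ibd)
    manifest.record("ibd", dt, report["ibd"])

    report["manifest"] = {"seed": manifest.seed, "version": manifest.version,
                          "stages": manifest.stages}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        config.to_text(outdir / "config.txt")
    return report
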