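"""One-call driver for the standard CLI chain on a synthetic cohort.

Convenience wrapper used by scripts and tests: simulate → phenotype →
quantify → phenotype-call → tls-detect → tls-cluster → maturation → report,
all under one seed.
"""

from __future__ import annotations

from pathlib import Path

from .cli import run_cli
from .errors import DependencyError


def run_standard_pipeline(workdir: str | Path, seed: int,
                          n_patients: int = 4) -> dict[str, Path]:
    """Run every stage on a freshly simulated cohort; returns artifact
    paths keyed by stage output."""
    workdir = Path(workdir)
    cohort = workdir / "cohort"
    paths = {
        "cohort": cohort,
        "densities": workdir / "densities.csv",
        "calls": workdir / "phenotype_calls.csv",
        "records": workdir / "tls_records.csv",
        "model": workdir / "tls_model.json",
        "labeled": workdir / "tls_records_labeled.csv",
        "maturation": workdir / "maturation.csv",
        "report": workdir / "report.json",
    }
    steps = [
        ["simulate", "--out", str(cohort), "--seed", str(seed),
         "--n-patients", str(n_patients)],
        ["phenotype", "--cohort-dir", str(cohort)],
        ["quantify", "--cohort-dir", str(cohort),
         "--out", str(paths["densities"])],
        ["phenotype-call", "--densities", str(paths["densities"]),
         "--out", str(paths["calls"])],
        ["tls-detect", "--cohort-dir", str(cohort),
         "--out", str(paths["records"])],
        ["tls-cluster", "--records", str(paths["records"]),
         "--model-out", str(paths["model"]),
         "--records-out", str(paths["labeled"]),
         "--seed", str(seed), "--k-mode", "fixed:5"],
        ["maturation", "--records", str(paths["labeled"]),
         "--out", str(paths["maturation"])],
        ["report", "--cohort-dir", str(cohort),
         "--densities", str(paths["densities"]),
         "--phenotype-calls", str(paths["calls"]),
         "--tls-records", str(paths["labeled"]),
         "--maturation", str(paths["maturation"]),
         "--out", str(paths["report"]), "--seed", str(seed)],
    ]
    for argv in steps:
        rc = run_cli(argv)
        if rc != 0:
            raise DependencyError(f"pipeline stage failed: {argv[0]}")
    return paths
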