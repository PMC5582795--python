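#!/usr/bin/env python
"""Fit both divergence models to the simulated family from step 01.

Runs the full pipeline (site mask, inter-cluster rooting, Fitch counts and
root states, type-I and type-II maximum-likelihood fits, site posteriors,
Q > 0.67 site calls) and writes the report bundle under results/divergence/.
"""

from pathlib import Path

from paradiverge import RunConfig, run_divergence

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    fam = ROOT / "family"
    if not (fam / "alignment.fasta").exists():
        raise SystemExit("run analysis/01_simulate_family.py first")
    cfg = RunConfig(
        alignment=str(fam / "alignment.fasta"),
        clusters=str(fam / "clusters.tsv"),
        tree=str(fam / "tree.nwk"),
        outdir=str(ROOT / "divergence"),
        seed=1,
    )
    result = run_divergence(cfg)
    t1, t2 = result.type1, result.type2
    print(f"theta_I  = {t1.theta_hat:.4f} +/- {t1.se_theta:.4f} (LRT p = {t1.p_value:.3g})")
    print(f"theta_II = {t2.theta_hat:.4f} +/- {t2.se_theta:.4f} (LRT p = {t2.p_value:.3g})")
    print(f"{len(result.called_sites)} sites called at Q_II > 0.67 "
          f"(true type-II fraction was 0.236)")
    print(f"outputs in {cfg.outdir}")


if __name__ == "__main__":
    main()
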