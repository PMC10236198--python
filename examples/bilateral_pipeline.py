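"""End-to-end bilateral comparison on an idealized venous bifurcation.

Two runs of the full chain (geometry -> inflow -> pulsatile field -> WSS/OSI
-> topology -> report): a symmetric null, and a run with a vortex planted in
the left outflow channel.  The lateralization call follows the mean
critical-point count, the metric consistently elevated on the side that goes
on to develop stenosis.
"""
import warnings

from venoflow import PipelineConfig, run_pipeline

warnings.filterwarnings("ignore")


def show(tag, report):
    print(f"--- {tag} ---")
    for side in ("left", "right"):
        m = report.sides[side]
        print(
            f"  {side:5s}: WSSmean {m.wss_mean:7.3f} dyne/cm^2  "
            f"OSImean {m.osi_mean:7.4f}  corelen {m.corelen:5.2f} cm  "
            f"nCrPoints {m.n_cr_points_mean:4.2f}"
        )
    ratios = {k: v["value"] for k, v in report.ratios.items()}
    print(f"  fold ratios : {ratios}")
    print(f"  lateralization: {report.lateralization}\n")


null = run_pipeline(PipelineConfig(seed=1, resolution=16, n_phases=5))
show("symmetric null", null)

swirl = run_pipeline(
    PipelineConfig(seed=1, resolution=16, n_phases=5, swirl_side="left")
)
show("left-sided planted vortex", swirl)

print(
    "In the null case every fold ratio is 1 and no side is called.  With the "
    "planted\nvortex the first-order WSSmean stays within 1.3-fold between "
    "sides while corelen\nand the critical-point count diverge (ratios "
    "against a zero contralateral value\nare flagged None, as the raw pair "
    "is the meaningful report), and the left side\nis called."
)
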