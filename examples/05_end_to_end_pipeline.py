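"""The full workflow in one call: simulate -> extract -> select -> train ->
evaluate -> compare, with every intermediate persisted.

Runs a small image-phantom study with a reduced filter bank so it finishes
in about a minute; drop the ``bank=`` line to use the full 20-image bank.
"""

from plnm_radiomics import BankConfig, RunConfig, SimConfig, run_end_to_end
from plnm_radiomics.evaluation import format_report

config = RunConfig(
    out_dir="scratch/e2e_run",
    seed=0,
    sim=SimConfig(n_train_pos=6, n_train_neg=12, n_internal=10, n_external=10,
                  prevalence_internal=0.3, prevalence_external=0.3, seed=0),
    bank=BankConfig(log_sigmas_mm=(1.0,), pointwise=("square",),
                    gradient=False, lbp3d=False, wavelet=False),
    n_repeats=1,
)
report = run_end_to_end(config)
print(format_report(report))
print(f"\nartifacts (feature tables, traces, models, report) in {config.out_dir}/")
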