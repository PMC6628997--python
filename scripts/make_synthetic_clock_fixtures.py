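"""Regenerate the synthetic packaged clock coefficient files.

The real published coefficient tables are distributed as journal
supplements; the files under ``src/placlock/data`` are synthetic
stand-ins that reproduce their documented structure — probe counts
(robust clock 558 CpGs, control clock 546, refined clock 395, fetal
sex-classifier 220), the 199-probe overlap between the robust and control
clocks, and the refined clock's containment in the robust clock — with
deterministic pseudo-random probe ids and coefficients. They exercise the
coefficient-table plumbing; their predictions are not gestational ages.

Run from the repository root: ``python scripts/make_synthetic_clock_fixtures.py``
"""

import pathlib

import numpy as np

from placlock.types import ClockModel
from placlock.io import write_clock

DATA = pathlib.Path(__file__).resolve().parents[1] / "src" / "placlock" / "data"

N_RPC, N_CPC, N_REFINED, N_SEX = 558, 546, 395, 220
N_OVERLAP = 199  # robust/control shared probes
SEED = 20190624


def main() -> None:
    rng = np.random.default_rng(SEED)
    pool = rng.choice(450_000, size=N_RPC + (N_CPC - N_OVERLAP) + N_SEX,
                      replace=False) + 1
    ids = [f"cg{int(i):08d}" for i in pool]
    rpc_ids = ids[:N_RPC]
    cpc_ids = (list(rng.choice(rpc_ids, size=N_OVERLAP, replace=False))
               + ids[N_RPC:N_RPC + (N_CPC - N_OVERLAP)])
    refined_ids = list(rng.choice(rpc_ids, size=N_REFINED, replace=False))
    sex_ids = ids[N_RPC + (N_CPC - N_OVERLAP):]

    def coefs(id_list, scale):
        return {p: float(w) for p, w in
                zip(id_list, rng.normal(0.0, scale, size=len(id_list)))}

    DATA.mkdir(parents=True, exist_ok=True)
    write_clock(ClockModel("rpc_synthetic", intercept=24.0,
                           coefficients=coefs(rpc_ids, 2.0)),
                DATA / "rpc_synthetic.csv")
    write_clock(ClockModel("cpc_synthetic", intercept=25.0,
                           coefficients=coefs(cpc_ids, 2.0)),
                DATA / "cpc_synthetic.csv")
    write_clock(ClockModel("refined_rpc_synthetic", intercept=38.5,
                           coefficients=coefs(refined_ids, 1.0)),
                DATA / "refined_rpc_synthetic.csv")
    write_clock(ClockModel("sex_classifier_synthetic", intercept=0.0,
                           coefficients=coefs(sex_ids, 4.0)),
                DATA / "sex_classifier_synthetic.csv")
    print(f"wrote 4 synthetic coefficient files to {DATA}")


if __name__ == "__main__":
    main()
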