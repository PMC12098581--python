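#!/usr/bin/env python
"""Generate the two synthetic study datasets.

Writes (a) a two-class, one-factor dataset whose class membership depends on
the binned-age covariate — the regime the EM track estimates — and (b) a
ten-profile dataset with age-varying profile prevalence for the deep
clustering track. Both use the 54-item battery schema with a trimodal age
distribution on [4, 16].
"""

import json
from pathlib import Path

import numpy as np

from cogmix import synthetic as syn

OUT = Path(__file__).resolve().parents[1] / "results"
DATA = Path(__file__).resolve().parents[1] / "scratch"
SEED = 20250509
N = 2570


def main() -> None:
    OUT.mkdir(exist_ok=True)
    DATA.mkdir(exist_ok=True)
    truth = syn.default_fmm_truth()
    two_class = syn.simulate_fmm1(N, truth, seed=SEED)
    two_class.to_csv(DATA / "two_class_data.csv",
                     labels_path=DATA / "two_class_labels.csv")

    bank = syn.default_profile_bank()
    multi = syn.simulate_profiles(N, bank, seed=SEED + 1)
    multi.to_csv(DATA / "multi_profile_data.csv",
                 labels_path=DATA / "multi_profile_labels.csv")

    bins, _ = syn.bin_ages(two_class.ages)
    meta = {
        "seed": SEED,
        "n": N,
        "two_class": {
            "class_counts": np.bincount(two_class.true_labels).tolist(),
            "age_bin_counts": np.bincount(bins, minlength=3).tolist(),
            "alpha": list(truth.class_factor_means),
            "gamma0": list(truth.gamma0),
            "gamma1": list(truth.gamma1),
        },
        "multi_profile": {
            "profile_counts": np.bincount(multi.true_labels,
                                          minlength=bank.n_profiles).tolist(),
            "n_profiles": bank.n_profiles,
        },
    }
    (OUT / "simulation_meta.json").write_text(json.dumps(meta, indent=2))
    print(f"two-class dataset: n={N}, class counts "
          f"{meta['two_class']['class_counts']}, age bins "
          f"{meta['two_class']['age_bin_counts']}")
    print(f"multi-profile dataset: profile counts "
          f"{meta['multi_profile']['profile_counts']}")


if __name__ == "__main__":
    main()
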