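"""Independent brute-force reference for the five-part Price partition.

Recomputes each component with explicit loops over the lost / shared /
gained species sets, term by term from first principles, sharing no code
with the package implementation:

* richness loss = expected change if every lost species had the baseline
  community mean function (-#lost * z-bar);
* identity loss = observed change from losses minus that expectation;
* richness gain / identity gain symmetrically with the comparison mean;
* the persisting-species term is the summed observed change of shared
  species.
"""
from __future__ import annotations


def brute_force_partition(z_baseline: dict, z_comparison: dict) -> dict:
    lost = [sp for sp in z_baseline if sp not in z_comparison]
    gained = [sp for sp in z_comparison if sp not in z_baseline]
    shared = [sp for sp in z_baseline if sp in z_comparison]

    s = len(z_baseline)
    s_prime = len(z_comparison)
    zbar = sum(z_baseline.values()) / s if s else 0.0
    zbar_prime = sum(z_comparison.values()) / s_prime if s_prime else 0.0

    observed_loss = -sum(z_baseline[sp] for sp in lost)
    expected_loss = -len(lost) * zbar
    observed_gain = sum(z_comparison[sp] for sp in gained)
    expected_gain = len(gained) * zbar_prime
    cde = sum(z_comparison[sp] - z_baseline[sp] for sp in shared)

    return {
        "sre_loss": expected_loss,
        "sie_loss": observed_loss - expected_loss,
        "sre_gain": expected_gain,
        "sie_gain": observed_gain - expected_gain,
        "cde": cde,
        "delta_function": sum(z_comparison.values()) - sum(z_baseline.values()),
    }
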