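# Examples

Short narrative scripts, one per capability; each builds or simulates a
small input, runs the method, and prints what it computes.

| script | capability |
| --- | --- |
| `01_simulate_dataset.py` | synthetic study generation with ground truth |
| `02_call_tss_clusters.py` | TSS cluster calling and region assignment |
| `03_quantify_te.py` | TE arithmetic and leave-one-fraction-out robustness |
| `04_test_divergence.py` | bootstrap testing of pairwise TE divergence |
| `05_utr_features.py` | 5'UTR cis-element extraction and folding |
| `06_association.py` | length-matched feature/TE association battery |
| `07_model_variance.py` | MARS models and variance decomposition |

Run any of them from the repository root, e.g.
`python examples/06_association.py`.
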