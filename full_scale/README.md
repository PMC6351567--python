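# Full-scale tier

Full-size production runs: 1e8–2e8 integration steps per stage, 20
replicas, systems up to ~8200 beads. These are cluster-scale workloads
(days of CPU per configuration); they are deliberately kept out of the
default `tests/` suite, which covers the same physics at desk scale.

## Configurations

| config | system | quantity checked |
|---|---|---|
| `ring-brush-{left,right}.yaml` | ring brush N=200, Ns=10, D=18a, L=45a | sub-ensemble ⟨Wr⟩ = −1.03 / +1.02, σ_Wr = 1.58 / 1.59; pooled ⟨Wr⟩ = 0.01, σ_Wr = 2.07 |
| `linear-brush-{left,right}.yaml` | linear brush N=200, Ns=40, D=30a, L=50a | kinetically separated sub-ensembles; double-peaked pooled P(Wr) |
| `stiff-chain-confined.yaml` | semiflexible chain N=25, D=4a, L=20a, ℓp=100a | double-peaked P(Wr) |
| `ring-brush-cg.yaml` | ring brush N=300, Ns=30, D=34a, L=70a | coarse-graining turns the single-peaked pooled sum double-peaked |

## Running

```sh
for cfg in configs/*.yaml; do
    writhesim pipeline --config "$cfg" --out "runs/$(basename "$cfg" .yaml)"
done
python -m pytest test_full_scale.py
```

`test_full_scale.py` asserts the sub-ensemble means within ±0.15 and the
standard deviations within ±0.2 (the replica-to-replica spread of the
full-scale ensembles) against the summaries written into `runs/`.
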