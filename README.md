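# transfernet

Social network analysis of interhospital emergency-department (ED) transfer
flows.

When an ED transfers a patient, the sending and receiving hospitals form a
directed tie; over a study period these ties make up a national referral
network whose shape tells you whether emergency care is *regionalized* —
patients flowing to designated hub ("base") hospitals within their region —
or fragmented. `transfernet` turns patient-level transfer records into
directed valued hospital networks and computes the statistics used to
monitor that structure, for health-services researchers and policymakers
working with transfer registries.

## The model

Each hospital ED is a node. Each distinct ordered pair (sender → receiver)
with at least one transfer is an arc, valued by its transfer count. On this
directed graph with N nodes and L arcs the package computes, natively:

* **degrees** — in-degree and out-degree count *distinct* transfer-in /
  transfer-out partners (binary view); net connectivity = in − out
  separates "receivers" (> 0) from "distributors" (< 0);
* **betweenness** — Brandes' shortest-path betweenness on the directed,
  unweighted graph, standardized by (N−1)(N−2);
* **closeness** — (N−1)/farness, farness being the sum of geodesic
  distances; unreachable targets follow a documented, switchable convention;
* **local clustering** — arcs observed among a node's neighbors (union of
  in- and out-neighbors) over the k(k−1) possible;
* **density** L/(N(N−1)), **in-degree centralization**
  Σᵢ(d_max − dᵢ)/(N−1)² (exactly 1 for an inward star), average clustering,
  the **dyad census** (mutual/asymmetric/null pairs) and **dyadic
  reciprocity** mutual/(mutual+asymmetric).

Around the metrics sit the pipeline stages: record cleaning and a Table-1
style descriptive summary; skeleton extraction (arc-weight thresholds such
as ≥ 36 transfers per 3 years ≈ one per month); per-year slicing for
temporal trends; an OLS regression of in-degree on served population; a
two-proportion z-test comparing direct-discharge rates for transfers sent
by top-distributor EDs; sociogram rendering; and a calibrated synthetic
generator that emulates a regionalized hub-and-spoke system with known
ground truth (real national transfer registries are access-restricted).

## Worked example

```python
import transfernet as tn

registry, records, truth = tn.simulate(seed=42)       # ~200 hospitals, 14 regions
net = tn.build_network(records, registry)
m = tn.network_metrics(net)
print(f"nodes={m.n_nodes} ties={m.n_arcs} transfers={net.total_transfers}")
print(f"density={m.density:.3f} in-degree centralization={m.in_degree_centralization:.2f}")
print(f"reciprocity={m.reciprocity:.2f} (mutual {m.census.mutual} / asymmetric {m.census.asymmetric})")

skeleton = tn.extract_skeleton(net, min_weight=36)    # robust ties only
print(f"skeleton: nodes={skeleton.n_nodes} ties={skeleton.n_arcs}")

full = tn.build_network(records, registry, include_isolates=True)
fit = tn.degree_population_regression(tn.degree_metrics(full), registry)
print(f"in-degree ~ population: slope={fit.slope:.2f}/million (SE {fit.slope_se:.2f}), p={fit.p_value:.1e}")

cmp = tn.distributor_discharge_comparison(records, tn.degree_metrics(net))
print(f"distributor discharge: {cmp.percent_a}% vs {cmp.percent_b}% (p={cmp.p_value:.3f})")
```

prints

```
nodes=192 ties=1064 transfers=59604
density=0.029 in-degree centralization=0.11
reciprocity=0.21 (mutual 185 / asymmetric 694)
skeleton: nodes=185 ties=349
in-degree ~ population: slope=5.40/million (SE 0.17), p=1.3e-79
distributor discharge: 6.0% vs 5.4% (p=0.087)
```

Reading this: the generated system is sparse (2.9% of possible ties exist),
mostly one-way (only 21% of connected hospital pairs transfer in both
directions), and regionalized — each additional million residents served
predicts ~5.4 extra transfer-in partners, recovering the generator's
planted slope of 5.5 within one standard error, and transfers sent by the
most distributor-like EDs are discharged directly at the receiving ED
slightly more often (6.0% vs 5.4%), the planted outcome difference.

The same pipeline is available from the shell:

```bash
transfernet --seed 42 --out-dir out simulate
transfernet --out-dir out build out/transfers.csv out/registry.csv
transfernet --out-dir out metrics out/edgelist.csv --registry out/registry.csv
transfernet --out-dir out plot out/edgelist.csv --registry out/registry.csv --min-weight 36
```

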