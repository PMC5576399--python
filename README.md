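# epiproducts

Compartmental epidemic models as an algebra of **products**.

Structured epidemic models — metapopulation, age-structured, gendered,
risk-stratified, multistrain — are usually written down one at a time, by
hand. Yet almost all of them share a design pattern: they are *products*
of simple factor models, in the same sense that a grid graph is the
Cartesian product of two paths. `epiproducts` makes that pattern
executable. It represents a compartmental model as a labeled directed
multigraph with symbolic rates, composes models with Cartesian, extended
Cartesian, and strong products, and derives ODE systems, Graphviz
diagrams, and numeric trajectories (deterministic or stochastic) from the
result. It is aimed at modelers who want to generate and compare whole
families of structured models systematically — for model development and
for structural sensitivity analysis — rather than rebuild each variant by
hand.

## The model algebra

A model is a directed multigraph: vertices are compartments (counts of
individuals), arcs are transitions labeled with symbolic rates, and two
distinguished pseudo-vertices SOURCE and SINK carry recruitment and
removal flows. Products come in three strengths:

* **Cartesian product of linear models.** For factor states
  $A_i$ and $B_j$, the product states are pairs $(A_i, B_j)$; a factor
  transition $B_j \to B_{j'}$ at rate $\gamma$ becomes a transition
  $(A_i,B_j) \to (A_i,B_{j'})$ at rate $\gamma_i$ for every level $i$,
  and similarly for inflows $\Lambda \mapsto \Lambda_i$ and outflows
  $\mu \mapsto \mu_i$. With undifferentiated rates this is exactly the
  Kronecker sum $M_A \oplus M_B$ of the factor transition matrices.

* **Extended Cartesian product.** Epidemic rates interact:
  a transmission rate $f(X_s, Z_1, \dots, Z_k)$ depends on compartments
  other than its source. The product generates one arc per choice of
  descendants of the interaction arguments, *independently* of the
  source's level. For the SI model ($\dot S = -\beta S I$) crossed with
  an $n$-community model this produces transitions
  $S_i \to I_i$ at rates $\beta_{ij} S_i I_j$ for every $j$ — the
  classical multi-community (Watson) model

  $$\dot S_i = -\textstyle\sum_j \beta_{ij} S_i I_j, \qquad
    \dot I_i = \textstyle\sum_j \beta_{ij} S_i I_j - \gamma_i I_i.$$

* **Strong product.** Adds diagonal arcs in which transitions from
  *distinct* factors occur simultaneously — e.g. co-transmission of two
  pathogen strains to a fully susceptible person in a single encounter
  ($S \to I_{12}$), which no Cartesian product can express.

A `ProductRule` refines a product: which subscripts each parameter
receives (`beta_be`, `c_bc`, `p_bcef`, …), which candidate arcs are kept,
which simultaneous-transition sets are biologically admissible, and how
population-size aggregates like $N = S + I$ re-scope per level
($N_M = S_M + I_M$) or stay global (multistrain models).

## Worked example

```python
from epiproducts import zoo, ode_system, io

watson = zoo.build("watson", n=2)   # SI x 2 communities
print(repr(watson))
print(io.odes_to_text(ode_system(watson.aggregate_parallel_arcs())))
```

prints

```
<CompartmentalModel 'si x community2': 4 compartments, 6 arcs>
dS_1/dt = -I_1*S_1*beta_11 - I_2*S_1*beta_12
dS_2/dt = -I_1*S_2*beta_21 - I_2*S_2*beta_22
dI_1/dt = I_1*S_1*beta_11 - I_1*gamma_1 + I_2*S_1*beta_12
dI_2/dt = I_1*S_2*beta_21 + I_2*S_2*beta_22 - I_2*gamma_2
```

The 4 compartments are the pairs (disease state, community); the 6 arcs
are four transmission arcs — two of them *parallel* arcs $S_1 \to I_1$
(within-community and cross-community infection), merged by
`aggregate_parallel_arcs()` into the single rate
$(\beta_{11} I_1 + \beta_{12} I_2)S_1$ — plus one removal arc per
community. The printed system is the Watson model with $n = 2$.

The zoo (`epiproducts.zoo.registry()`) holds thirteen reference
constructions, including SI with demography in communities, SIR with
compartmental aging (with vertical-transmission and immune-at-birth
inflows), risk- and gender-structured STI models, the joint
leprosy–tuberculosis product, the two-strain SIS strong product with
co-transmission, and a four-factor gonorrhea screening model (16
compartments) with its full family of $2^3$ partial products.

A CLI mirrors the library:

```
epiproducts product --kind cartesian -o watson.yaml si.yaml community2.yaml
epiproducts ode watson.yaml --latex
epiproducts render watson.yaml -o watson.dot
epiproducts simulate watson.yaml --param beta_11=0.1 ... --init S_1=99 --init I_1=1
epiproducts family --base sis.yaml exposure.yaml gender.yaml risk.yaml --outdir family/
```

Model files are declarative YAML (compartments, arcs with infix rate
strings, aggregates) and round-trip losslessly, parallel arcs included.

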