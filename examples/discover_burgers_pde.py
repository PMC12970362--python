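"""Discover a PDE from field snapshots.

Simulates the viscous Burgers equation u_t = -u u_x + 0.1 u_xx by Fourier
collocation, builds a weak-form library (powers of u, spatial derivatives up
to fourth order moved onto the separable test function, and the conservative
convective term 0.5 d(u^2)/dx), and prunes it.  The two surviving terms give
the convection coefficient (-1) and the diffusion coefficient (0.1).
"""

from slicdd.workflows import discover_pde_system

model, scores, problem = discover_pde_system("burgers", criterion="slic")
for term, coef in zip(model.term_labels, model.coefficients[:, 0]):
    if abs(coef) > 1e-6:
        print(f"  d(u)/dt  <-  {coef:+.4f} * {term}")
print(f"(selected from {len(model.term_labels)} candidate terms over "
      f"{problem.theta_weak.n} space-time windows)")
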