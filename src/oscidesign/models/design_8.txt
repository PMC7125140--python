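# design 8: design_3 plus one saturating transcriptional inhibition —
# Sic1 represses CLB5, CLB3 and CLB2 synthesis (strength K_sc).
# The denominator is carried as the algebraic auxiliary below so
# that its two regimes enter the dominance decomposition.
@name design_8
@species Sic1=s Clb5=x Clb3=y Clb2=z
@peak_order Sic1 Clb5 Clb3 Clb2
x' = v_x*K_sc*D_sc^-1 - beta_x*x - gamma_yx*y*x - gamma_zx*z*x - epsilon*c_x
y' = v_y*K_sc*D_sc^-1 + alpha_xy*x + alpha_yy*y - beta_y*y - gamma_yy*y^2 - gamma_zy*z*y - epsilon*c_y
z' = v_z*K_sc*D_sc^-1 + alpha_xz*x + alpha_yz*y + alpha_zz*z - beta_z*z - gamma_zz*z^2 - epsilon*c_z
s' = v_s - beta_s*s - delta*c_x - delta*c_y - delta*c_z
c_x = K_A*x*s
c_y = K_A*y*s
c_z = K_A*z*s
D_sc = K_sc + s
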