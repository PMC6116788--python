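# Image-recognition preset: published connectivity / weight-initialization /
# STDP parameter tables for the static-image task, at desk-scale liquid size
# (400 neurons, 4:1 excitatory:inhibitory) on 12x12 synthetic glyphs.
task: image-like
duration: 350.0          # presentation interval (ms)
t_step: 0.5
n_tags: 1                # tag each neuron with its single most-active class
n_liquids: 1
partition_scheme: vertical-halves
partition_overlap: 4     # shared columns between the two image halves
p_inp_e_ensemble: 50.0   # input connectivity per liquid when n_liquids > 1
seed: 0
liquid:
  n_inp: 144             # overridden per partition at build time
  n_e: 320
  n_i: 80
  p_inp_e: 30.0          # single-liquid input connectivity (%)
  p_ee: 1.0
  p_ei: 5.0
  p_ie: 30.0
  p_ii: 1.0
  w_init_min: 0.003
  w_init_max: 0.303
  w_ee: 1.0
  w_ei: 10.0
  w_ie: 1.0
  w_ii: 1.0
  seed: 0
stdp:
  eta: 0.005
  tau: 15.0
  stdp_offset: 0.4
  mu: 0.9
  w_max: 1.0
  w_min: 0.0
lif_e:
  tau_mem: 100.0
  v_rest: -65.0
  v_reset: -65.0
  theta_base: -52.0
  theta_plus: 0.05
  tau_theta: 1.0e+7
  t_refrac: 5.0
  tau_syn_e: 2.0
  tau_syn_i: 1.0
lif_i:
  tau_mem: 10.0
  v_rest: -65.0
  v_reset: -45.0
  theta_base: -40.0
  theta_plus: 0.0
  tau_theta: 1.0e+7
  t_refrac: 2.0
  tau_syn_e: 2.0
  tau_syn_i: 1.0
schedule:
  n_examples: 2000
  seed: 0
synthetic:
  n_classes: 4
  input_shape: [12, 12]
  noise_level: 0.1
  samples_per_class: 10
  seed: 0
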