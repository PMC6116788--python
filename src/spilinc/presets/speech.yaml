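# Speech-recognition preset: published connectivity / weight-initialization /
# STDP parameter tables for the temporal (cochleagram-like) task, at
# desk-scale liquid size (320 neurons, 3:1 excitatory:inhibitory) on 20-channel
# x 100-frame synthetic intensity matrices.
task: speech-like
duration: 750.0          # presentation interval (ms)
t_step: 0.5
n_tags: 2                # tag each neuron with its two most-active classes
n_liquids: 1
partition_scheme: channel-blocks
partition_overlap: 5     # block size = ceil(channels/n_liquids) + overlap
p_inp_e_ensemble: 25.0
seed: 0
liquid:
  n_inp: 20              # overridden per partition at build time
  n_e: 240
  n_i: 80
  p_inp_e: 25.0
  p_ee: 0.5
  p_ei: 5.0
  p_ie: 20.0
  p_ii: 0.5
  w_init_min: 0.005
  w_init_max: 0.505
  w_ee: 1.0
  w_ei: 3.0
  w_ie: 1.0
  w_ii: 1.0
  seed: 0
stdp:
  eta: 0.0001
  tau: 15.0
  stdp_offset: 0.0       # potentiation-only: weights never depressed
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
  n_examples: 400
  seed: 0
synthetic:
  n_classes: 4
  input_shape: [20, 100]
  noise_level: 0.1
  samples_per_class: 10
  seed: 0
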