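{
  "invitro_benchmark_synthetic.fa": "fe0eb31da4f1bf25244b324c5afd36804f1dc5046c40916e23e1c09622fa5634",
  "invitro_dyads_synthetic.bed": "e29019683f2bd46e6e11abaa59c1328a6f5f103afabde316eb2a21e8d54b92b7"
}
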