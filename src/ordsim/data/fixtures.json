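{
 "endo_ss_cl1000": {
  "state": [
   -87.98602188772591,
   7.248572110414235,
   7.248656515072308,
   144.57661875623532,
   144.576592202395,
   8.54335149692132e-05,
   8.432234975184147e-05,
   1.610048033024703,
   1.5641768097498343,
   0.007355862962419733,
   0.6975567664257126,
   0.6975400161627016,
   0.6974462968205295,
   0.4543046704284009,
   0.6973834720365292,
   0.0001888306257417366,
   0.5009144637797147,
   0.269670206104623,
   0.0010021701360403998,
   0.9995529361572464,
   0.5912670985132273,
   0.0005106330039199807,
   0.9995529435084464,
   0.6440253777916953,
   2.3495993384500747e-09,
   0.9999999908355178,
   0.9109829982062334,
   0.9999999908355797,
   0.9998226985606331,
   0.9999770530067451,
   0.002674952422324761,
   0.9999999908326654,
   0.9999999908328359,
   8.088725159813566e-06,
   0.45059404639674316,
   0.26974533424373587,
   0.00019319040559844617,
   0.9967639133956765,
   2.469035112527214e-07,
   3.0847150384322713e-07,
   0.01233498560119854
  ],
  "metrics": {
   "apd90": 271.9757303313005,
   "nai": 7.248572110414235,
   "dvdt_max": 255.37766322842907
  },
  "meta": {
   "max_beats": 1000,
   "tol": 1e-06,
   "dt": [
    0.005,
    0.02,
    0.1
   ]
  }
 },
 "endo_ss_cl1000_camk_off": {
  "state": [
   -87.98894238398087,
   7.221350225583745,
   7.221441301692876,
   144.73006840127468,
   144.73004270439043,
   9.025889972316098e-05,
   8.923340960743597e-05,
   1.3298459702566179,
   1.2845068751245545,
   0.007353707687703025,
   0.6976577680507691,
   0.6976326858658037,
   0.697496654982453,
   0.45439326845110156,
   0.6974094058871211,
   0.00018872614070190456,
   0.5012624437899623,
   0.2709587656835287,
   0.0010019754293616736,
   0.9995531365552419,
   0.5949822035763528,
   0.0005105337467553614,
   0.9995531474792583,
   0.6485071697942012,
   2.347995471529129e-09,
   0.9999999908418817,
   0.9136332130171639,
   0.9999999908419731,
   0.999836451233322,
   0.9999793426049726,
   0.0033224918126594652,
   0.999999990837697,
   0.9999999908379443,
   8.080050198892173e-06,
   0.4474176219001953,
   0.26203074795917136,
   0.00019315506674607595,
   0.9967633270756688,
   9.402228567554622e-08,
   1.1741712834645958e-07,
   0.0
  ],
  "metrics": {
   "apd90": 264.1833097790369,
   "n_state_vars": 31
  },
  "meta": {
   "max_beats": 1000
  }
 }
}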