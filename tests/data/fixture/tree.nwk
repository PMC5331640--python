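(((((OTU_048:0.0006991209695536012,OTU_073:0.04447750472619826):1.0094819272385112,(OTU_023:0.1894008174896214,OTU_098:0.8699605117632544):4.704996789736144):0.47173138585886876,(((OTU_049:0.4965629065273913,OTU_099:0.0857863490107539):1.5637365733442161,(OTU_024:0.5080595424074739,OTU_074:0.12334843306084159):1.0972726471966905):0.10642863163450879,(OTU_050:0.4331095108846043,(OTU_075:1.3456856100590797,(OTU_025:0.6119364107484113,OTU_100:0.05634601704364809):0.3670554527437774):0.13338099771318282):0.058813817077424335):0.419727952239162):1.3591076093297674,((((OTU_004:0.6187020000442978,OTU_029:0.9553031304044972):0.06749992356334494,(OTU_054:0.9008710427952277,(OTU_079:1.6422196859692653,OTU_104:0.05315200513927177):0.03160421953038662):0.15311786276580594):0.5371729009812317,(((OTU_091:0.3208292449153413,((OTU_016:0.16166361888739167,OTU_066:0.7872211759401457):0.09570624595156549,(OTU_041:1.8552059168956028,OTU_116:1.377030566375686):2.199239022155137):0.7526622077498217):0.2662032793129534,((OTU_026:0.43757516432206617,OTU_076:1.9619906902448492):0.4652933306644096,(OTU_051:0.8777749652013758,(OTU_001:1.0472168418378274,OTU_101:0.8202209153784054):0.524266782719344):1.7576346372767233):1.283249493549177):0.032059733807741256,((((OTU_033:0.7995763519546627,(OTU_008:0.8036104783610002,OTU_108:0.25342457840630905):0.1819398060420317):0.23630442391705644,(OTU_058:0.7358828262442806,OTU_083:2.016014700154725):0.35475659136199617):0.4964342801544842,(OTU_009:1.883744724643036,((OTU_059:1.4482392949243519,OTU_084:0.5737618666006002):0.7560885348746085,(OTU_034:0.9568456908184739,OTU_109:0.8969837604747738):0.5705045466794825):1.1260899090765248):3.4529033880494167):1.7781896605401364,(((OTU_027:2.9810133984082934,OTU_052:0.1355926458293349):0.7648381147413351,(OTU_077:0.45226841947254365,(OTU_002:1.296458245197184,OTU_102:1.30391504050791):0.9453669638177495):0.174243255946321):0.22455476227836801,((OTU_005:0.6366837961103083,(OTU_030:0.3274893874541691,(OTU_055:1.9291825828422708,(OTU_080:4.660053036595954,OTU_105:0.03893325080703048):0.08477580996665478):2.988370778662161):1.0581720658749352):1.9543237699773846,(OTU_003:0.05894232061630262,((OTU_053:0.5680643851036283,OTU_078:0.22889388578693223):0.8299703899710483,(OTU_028:0.750793884458566,OTU_103:0.8179760149714166):0.4811300168043823):0.9462960177132627):3.118032723309375):0.8379078743804134):0.41942095493919795):0.9131768105333732):0.6160647858861474):0.6444029834993578,((((OTU_017:0.6312656487602003,(OTU_067:0.8806705251186117,(OTU_117:1.294842853030425,(OTU_042:0.8464918512910853,OTU_092:0.23768253129522976):1.6124915791924095):0.07873615353951995):0.01036793064974696):1.7725378139107113,((OTU_014:0.4477989976433952,OTU_039:0.22043256028972025):0.7712020933274426,(OTU_064:0.0669625209910076,(OTU_089:1.1958237156650384,OTU_114:0.4296666492432087):0.5265058225506009):0.08994122837121726):0.693359285661385):0.7714385939324716,((OTU_021:1.5963960772848635,(OTU_096:1.61697655313637,(OTU_046:0.27726259263073005,OTU_071:0.2951246796243428):0.6317392308605323):0.9752296939650931):0.22858961800694363,(OTU_065:1.0498766430375424,(OTU_040:3.6476196529033955,(OTU_115:0.23753424714880786,(OTU_015:0.4908325526510219,OTU_090:0.6933982522978993):1.2739580273279394):0.6227642888651743):2.6516815391230883):0.9037152656553232):0.11043795071663637):0.7666912568322125,((OTU_097:0.005457642512527653,(OTU_047:0.29114304956711573,(OTU_022:0.8255793597428458,OTU_072:1.7430616414569562):0.7612713951453316):1.587355638503474):0.8460991250231056,(((OTU_068:0.8641427713521113,OTU_093:2.8097962932755114):1.0310516891236299,(OTU_018:1.9405697397691817,(OTU_043:0.05344964724414589,OTU_118:1.212747367118231):0.04896000152857885):0.07175979480507143):1.14394809607672,(OTU_056:0.8168651808993487,((OTU_006:0.027222744584072665,OTU_081:1.0535111295301745):0.3879060774457887,(OTU_031:2.0100731170672774,OTU_106:0.008334471860722897):0.9232246681933968):0.1343541805714031):1.054487598766351):0.32766419310837946):1.689849326462543):0.4400633033285922):0.0759346396767187):0.10881933606643628,(((OTU_110:0.2867821333101061,(OTU_085:0.47649473339264414,(OTU_060:0.5340037888201874,(OTU_010:0.576372487484653,OTU_035:0.55194087772384):4.409276743767722):1.3167467929957597):0.4305012297974928):0.5874190221355005,(OTU_111:0.3948526544568432,((OTU_036:0.2389252339953494,OTU_061:0.8261940031416711):1.5303418039441834,(OTU_011:1.5775504962571838,OTU_086:1.209420225675798):0.22460839973452906):1.6518868344408881):2.135817429485398):2.7648836530926926,((OTU_037:1.2092626311459316,(OTU_012:0.09493365873571648,(OTU_087:4.896286726796393,(OTU_062:4.099913183302013,OTU_112:0.1936765964244042):0.7950337629320535):0.11104490615028946):1.7060650025029465):0.13350792277201848,((OTU_119:0.4560178787084086,(OTU_094:3.498689816697127,(OTU_069:0.38656248244136665,(OTU_019:0.8639408539454225,OTU_044:0.1821172980981398):2.0249711996830775):0.5139080629451422):0.4978135341811902):0.05375298667326683,(((OTU_038:0.8990276823474517,OTU_088:1.893961400273544):0.6093414063529371,(OTU_113:0.6976224092552137,(OTU_013:0.6748147104142745,OTU_063:0.02264860959593484):0.06452988316880677):0.22027560889919284):1.0562641236552937,((OTU_045:0.01242077862144956,(OTU_120:0.606893389762617,(OTU_095:1.443499852908719,(OTU_020:0.877737493151121,OTU_070:1.2514606651903226):2.0417317840467684):0.31831887685351506):1.3829481882936583):0.9169704997262265,(OTU_007:2.8415133252401845,((OTU_057:1.9020835207414977,OTU_107:1.7202407527968178):0.12091293933767919,(OTU_032:3.3932617537205116,OTU_082:1.3476571529493448):0.7017809840874404):0.8340222306334564):2.0649628038368135):1.7121765192021208):0.40394067007484125):0.06483451360712345):0.2396100752643421):0.8068270249675449);
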